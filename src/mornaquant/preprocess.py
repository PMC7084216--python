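"""Read preprocessing: 3' adapter trimming, quality/length filtering and
collapsing into counted unique sequence tags."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .formats_io import ReadRecord

log = logging.getLogger(__name__)


@dataclass
class PreprocessParams:
    """Filter thresholds applied between trimming and tag collapsing.

    ``max_lowq_bases`` is the number of bases allowed below ``lowq_phred``
    (fixed at Phred 20).
    """

    adapter: Optional[str] = None
    min_len: int = 18
    max_len: int = 30
    mean_qual: float = 30.0
    max_lowq_bases: int = 2
    lowq_phred: int = 20
    min_count: int = 10

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass(frozen=True)
class SequenceTag:
    """A unique trimmed read sequence with its aggregated count in a sample."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")

    def __len__(self) -> int:
        return len(self.seq)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def trim_adapter(
    read: ReadRecord,
    adapter: Optional[str],
    error_rate: float = 0.1,
    min_overlap: int = 3,
) -> Optional[ReadRecord]:
    """Remove the best 3' adapter occurrence; ``None`` means discard.

    A partial adapter at the read end is allowed (>= ``min_overlap`` bases,
    mismatch fraction <= ``error_rate``); the quality string is trimmed in
    lockstep.  Reads where no adapter occurrence is found, or where the
    insert is empty, are discarded.  ``adapter=None`` disables trimming and
    returns the read unchanged (NOADAPTER mode).
    """
    if adapter is None:
        return read
    n = len(read.seq)
    best: Optional[tuple[int, int]] = None  # (score, start)
    for i in range(0, n - min_overlap + 1):
        k = min(len(adapter), n - i)
        mism = _hamming(read.seq[i : i + k], adapter[:k])
        if mism <= int(error_rate * k):
            score = k - 2 * mism
            if best is None or score > best[0]:
                best = (score, i)
    if best is None or best[1] == 0:
        return None
    i = best[1]
    return ReadRecord(read.id, read.seq[:i], read.qual[:i])


def quality_filter(read: ReadRecord, p: PreprocessParams) -> Optional[str]:
    """Return ``None`` when the read passes, else the first violated criterion
    among ``min_len``, ``max_len``, ``mean_qual``, ``max_lowq_bases``."""
    n = len(read.seq)
    if n < p.min_len:
        return "min_len"
    if n > p.max_len:
        return "max_len"
    phred = read.phred()
    if sum(phred) / n < p.mean_qual:
        return "mean_qual"
    if sum(1 for q in phred if q < p.lowq_phred) > p.max_lowq_bases:
        return "max_lowq_bases"
    return None


def collapse_tags(reads: Iterable[ReadRecord]) -> tuple[list[SequenceTag], int]:
    """Collapse reads into unique sequence tags with aggregated counts.

    Reads containing N are dropped (exact matching downstream is meaningless
    with ambiguous bases); the second return value counts them.  The sum of
    tag counts equals the number of input reads minus the N-dropped ones.
    """
    counts: Counter[str] = Counter()
    n_dropped = 0
    for r in reads:
        if "N" in r.seq:
            n_dropped += 1
            continue
        counts[r.seq] += 1
    if n_dropped:
        log.info("collapse_tags: dropped %d N-containing reads", n_dropped)
    tags = [SequenceTag(seq, c) for seq, c in sorted(counts.items())]
    return tags, n_dropped


def filter_low_count(
    tags: Iterable[SequenceTag], min_count: int
) -> tuple[list[SequenceTag], list[SequenceTag]]:
    """Partition tags into (kept, dropped): kept iff count >= min_count."""
    kept, dropped = [], []
    for t in tags:
        (kept if t.count >= min_count else dropped).append(t)
    return kept, dropped


@dataclass
class PreprocessStats:
    raw_reads: int = 0
    trim_discarded: int = 0
    n_dropped: int = 0
    quality_failed: dict = field(default_factory=dict)
    tags_total: int = 0
    tags_kept: int = 0
    tags_dropped_low_count: int = 0
    reads_in_kept_tags: int = 0
    reads_in_dropped_tags: int = 0

    @property
    def quality_failed_total(self) -> int:
        return sum(self.quality_failed.values())

    def as_dict(self) -> dict:
        return {
            "raw_reads": self.raw_reads,
            "trim_discarded": self.trim_discarded,
            "n_dropped": self.n_dropped,
            "quality_failed": dict(self.quality_failed),
            "tags_total": self.tags_total,
            "tags_kept": self.tags_kept,
            "tags_dropped_low_count": self.tags_dropped_low_count,
            "reads_in_kept_tags": self.reads_in_kept_tags,
            "reads_in_dropped_tags": self.reads_in_dropped_tags,
        }


def preprocess_sample(
    reads: Iterable[ReadRecord], p: PreprocessParams, noadapter: bool = False
) -> tuple[list[SequenceTag], PreprocessStats]:
    """Full preprocessing chain for one sample.

    Conservation: raw_reads == trim_discarded + quality_failed + n_dropped
    + sum of all tag counts.
    """
    stats = PreprocessStats()
    passed: list[ReadRecord] = []
    adapter = None if noadapter else p.adapter
    for read in reads:
        stats.raw_reads += 1
        trimmed = trim_adapter(read, adapter)
        if trimmed is None:
            stats.trim_discarded += 1
            continue
        reason = quality_filter(trimmed, p)
        if reason is not None:
            stats.quality_failed[reason] = stats.quality_failed.get(reason, 0) + 1
            continue
        passed.append(trimmed)
    tags, stats.n_dropped = collapse_tags(passed)
    stats.tags_total = len(tags)
    kept, dropped = filter_low_count(tags, p.min_count)
    stats.tags_kept = len(kept)
    stats.tags_dropped_low_count = len(dropped)
    stats.reads_in_kept_tags = sum(t.count for t in kept)
    stats.reads_in_dropped_tags = sum(t.count for t in dropped)
    return kept, stats
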