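"""Exact multi-locus genome matching of sequence tags and the multi-mapping
discard rule relative to precursor loci."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .formats_io import GenomeRef, revcomp
from .preprocess import SequenceTag


@dataclass
class MultimapParams:
    max_hits_enumerated: int = 50
    max_outside_loci: int = 5

    def __post_init__(self) -> None:
        if self.max_hits_enumerated <= self.max_outside_loci:
            raise ValueError("max_hits_enumerated must exceed max_outside_loci")


@dataclass(frozen=True)
class GenomeHit:
    chrom: str
    start: int  # 0-based half-open on the + strand axis
    end: int
    strand: str
    inside_precursor: bool = False


class GenomeIndex:
    """Seed-and-verify exact-match index over both strands.

    Forward k-mers of the genome are indexed; minus-strand occurrences of a
    query are found by searching its reverse complement, so a query q has a
    '-' hit at [s, e) iff revcomp(q) equals the + strand slice [s, e).
    """

    def __init__(self, genome: GenomeRef, k: int = 12):
        self.genome = genome
        self.k = k
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[i : i + k], []).append((chrom, i))

    def _find_forward(self, query: str) -> list[tuple[str, int]]:
        k = self.k
        if len(query) < k:
            # fall back to direct scan for very short queries
            out = []
            for chrom, seq in self.genome.sequences.items():
                pos = seq.find(query)
                while pos != -1:
                    out.append((chrom, pos))
                    pos = seq.find(query, pos + 1)
            return out
        hits = []
        for chrom, i in self._seeds.get(query[:k], ()):
            if self.genome.sequences[chrom][i : i + len(query)] == query:
                hits.append((chrom, i))
        return hits

    def find_all(self, query: str) -> list[GenomeHit]:
        """All exact occurrences of the query on both strands, sorted."""
        n = len(query)
        hits = [GenomeHit(c, i, i + n, "+") for c, i in self._find_forward(query)]
        hits += [GenomeHit(c, i, i + n, "-") for c, i in self._find_forward(revcomp(query))]
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return hits


def build_index(genome: GenomeRef, k: int = 12) -> GenomeIndex:
    return GenomeIndex(genome, k=k)


def _overlaps_precursor(
    hit: GenomeHit, precursor_intervals: Sequence[tuple[str, int, int, str]]
) -> bool:
    # strand-aware half-open intersection
    for chrom, start, end, strand in precursor_intervals:
        if hit.chrom == chrom and hit.strand == strand and hit.start < end and start < hit.end:
            return True
    return False


def locate_tag(
    tag: SequenceTag | str,
    index: GenomeIndex,
    precursor_intervals: Sequence[tuple[str, int, int, str]] = (),
    p: Optional[MultimapParams] = None,
) -> tuple[list[GenomeHit], bool]:
    """All exact genome occurrences of a tag, labelled ``inside_precursor``.

    Enumeration is capped at ``max_hits_enumerated``; the second return value
    flags whether the cap truncated the list.
    """
    p = p or MultimapParams()
    seq = tag.seq if isinstance(tag, SequenceTag) else tag
    hits = index.find_all(seq)
    capped = len(hits) > p.max_hits_enumerated
    if capped:
        hits = hits[: p.max_hits_enumerated]
    labelled = [
        GenomeHit(h.chrom, h.start, h.end, h.strand, _overlaps_precursor(h, precursor_intervals))
        for h in hits
    ]
    return labelled, capped


@dataclass(frozen=True)
class MultimapDecision:
    keep: bool
    genome_unmapped: bool = False
    n_outside: int = 0


def multimap_filter(
    hits: Iterable[GenomeHit], capped: bool, p: Optional[MultimapParams] = None
) -> MultimapDecision:
    """Discard tags hitting too many loci outside precursor genes.

    Discard iff the number of hits outside precursors strictly exceeds
    ``max_outside_loci``, or the enumeration cap was reached.  Tags with zero
    genome hits are kept but flagged ``genome_unmapped``: they may still
    align to precursors with (3') mismatches from non-templated additions.
    """
    p = p or MultimapParams()
    hits = list(hits)
    if capped:
        return MultimapDecision(keep=False, n_outside=sum(1 for h in hits if not h.inside_precursor))
    if not hits:
        return MultimapDecision(keep=True, genome_unmapped=True)
    n_outside = sum(1 for h in hits if not h.inside_precursor)
    return MultimapDecision(keep=n_outside <= p.max_outside_loci, n_outside=n_outside)
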