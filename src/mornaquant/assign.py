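"""Tag-to-precursor alignment, alignment blocks, sRNA definition and the
assignment of every alignment to an sRNA or to "unassigned"."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .hairpin import ExtendedPrecursor, FoldResult, arm_of, candidate_mor_geometry, project_star
from .preprocess import SequenceTag

CLASS_RANK = {"mir": 0, "new_mir": 1, "mor": 2, "loop": 3}
ARM_RANK = {"5p": 0, "3p": 1, "loop": 2}


@dataclass
class AssignParams:
    allowed_overhang: int = 3
    min_morna_len: int = 16
    morfilter: str = "conservative"  # conservative | permissive
    overlap_slack: int = 3
    star_min_paired_frac: float = 0.6
    star_overhang: int = 2
    star_max_annotated_overlap: int = 3

    def __post_init__(self) -> None:
        if self.allowed_overhang < 0:
            raise ValueError("allowed_overhang must be >= 0")
        if self.morfilter not in ("conservative", "permissive"):
            raise ValueError("morfilter must be 'conservative' or 'permissive'")


@dataclass(frozen=True)
class PrecursorAlignment:
    """A tag placed on an extended precursor with its mismatch positions
    (read-relative, 0-based from the 5' end)."""

    tag: SequenceTag
    precursor_id: str
    start: int  # extended-local
    mismatches: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.mismatches) > 2:
            raise ValueError("alignments are limited to 2 mismatches")

    @property
    def end(self) -> int:
        return self.start + len(self.tag.seq)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


def align_to_precursor(
    tag: SequenceTag, prec: ExtendedPrecursor, max_mm: int = 2
) -> list[PrecursorAlignment]:
    """All placements of the tag with Hamming distance <= ``max_mm``, reported
    in best-stratum order: only the minimum-mismatch stratum is returned
    (all 0-mm placements if any exist, else all 1-mm, else all 2-mm)."""
    seq, ref = tag.seq, prec.seq
    n, m = len(seq), len(ref)
    if n > m:
        return []
    strata: list[list[PrecursorAlignment]] = [[] for _ in range(max_mm + 1)]
    for off in range(m - n + 1):
        mism: list[int] = []
        window = ref[off : off + n]
        ok = True
        for i in range(n):
            if seq[i] != window[i]:
                mism.append(i)
                if len(mism) > max_mm:
                    ok = False
                    break
        if ok:
            strata[len(mism)].append(
                PrecursorAlignment(tag, prec.id, off, tuple(mism))
            )
    for stratum in strata:
        if stratum:
            return stratum
    return []


def filter_two_mismatch_3prime(aln: PrecursorAlignment) -> bool:
    """Keep 2-mismatch alignments only when both mismatches sit on the two
    3'-terminal read positions (non-templated additions); 0/1-mm alignments
    pass unconditionally."""
    if aln.n_mismatches < 2:
        return True
    n = len(aln.tag.seq)
    return set(aln.mismatches) == {n - 2, n - 1}


@dataclass
class AlignmentBlock:
    """Cluster of perfect alignments; its interval is the representative
    (most abundant) tag's placement."""

    precursor_id: str
    start: int
    end: int
    representative: PrecursorAlignment
    members: list[PrecursorAlignment] = field(default_factory=list)

    @property
    def total_count(self) -> int:
        return sum(a.tag.count for a in self.members)


def _seed_order_key(a: PrecursorAlignment) -> tuple:
    return (-a.tag.count, -len(a.tag.seq), a.start, a.tag.seq)


def build_blocks(alignments: Iterable[PrecursorAlignment]) -> list[AlignmentBlock]:
    """Greedy clustering of 0-mm alignments of one precursor into
    non-overlapping blocks.

    The highest-count unclustered tag (ties: longer tag, leftmost,
    lexicographic) seeds a block with its own interval; alignments
    overlapping the seed interval by more than 50% of their own length join.
    A later seed overlapping an earlier block is merged into it, so the
    final block intervals are pairwise non-overlapping.
    """
    pending = sorted(alignments, key=_seed_order_key)
    for a in pending:
        if a.n_mismatches:
            raise ValueError("build_blocks accepts only 0-mismatch alignments")
    raw: list[AlignmentBlock] = []
    while pending:
        seed = pending[0]
        members, rest = [], []
        for a in pending:
            ov = min(a.end, seed.end) - max(a.start, seed.start)
            if ov > 0.5 * len(a.tag.seq):
                members.append(a)
            else:
                rest.append(a)
        raw.append(
            AlignmentBlock(seed.precursor_id, seed.start, seed.end, seed, members)
        )
        pending = rest
    merged: list[AlignmentBlock] = []
    for block in raw:
        host = next(
            (b for b in merged if block.start < b.end and b.start < block.end), None
        )
        if host is None:
            merged.append(block)
        else:
            host.members.extend(block.members)
    merged.sort(key=lambda b: b.start)
    return merged


@dataclass(frozen=True)
class SrnaDefinition:
    """One of the up-to-five products of a precursor, extended-local coords."""

    precursor_id: str
    srna_class: str  # mir | new_mir | mor | loop
    arm: str  # 5p | 3p | loop
    start: int
    end: int
    name: str
    seq: str
    support_count: int = 0

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


def _srna_name(prec_name: str, srna_class: str, arm: str) -> str:
    from .isoform_quant import name_srna

    return name_srna(prec_name, srna_class, arm)


def _matches(block: AlignmentBlock, interval: tuple[int, int], tol: int) -> bool:
    return abs(block.start - interval[0]) <= tol and abs(block.end - interval[1]) <= tol


def _within(block: AlignmentBlock, window: tuple[int, int]) -> bool:
    return window[0] <= block.start and block.end <= window[1]


def finalize_srnas(
    ext: ExtendedPrecursor,
    fold_result: FoldResult,
    blocks: Sequence[AlignmentBlock],
    p: AssignParams,
    prec_name: str = "",
) -> list[SrnaDefinition]:
    """Turn alignment blocks into sRNA definitions for one precursor.

    (i) an annotated mature is expressed iff a block matches its interval
    within ``allowed_overhang`` at both ends; (ii) a block matching the
    star-projected interval defines a new miRNA at the block's own
    coordinates; (iii) a remaining block inside a moR window of length >=
    ``min_morna_len`` defines a moRNA; (iv) a block inside the loop interval
    defines the loop sRNA.  At most one definition per (class, arm); the
    highest-count block wins.
    """
    prec_name = prec_name or ext.id
    oh = p.allowed_overhang
    defs: dict[tuple[str, str], SrnaDefinition] = {}
    used: set[int] = set()

    annotated = [(name, iv, arm_of(iv, fold_result)) for name, iv in ext.matures.items()]
    ann_intervals = [iv for _, iv, _ in annotated]

    def claim(key: tuple[str, str], block: AlignmentBlock, interval: tuple[int, int]) -> None:
        current = defs.get(key)
        if current is not None and current.support_count >= block.total_count:
            return
        defs[key] = SrnaDefinition(
            precursor_id=ext.id,
            srna_class=key[0],
            arm=key[1],
            start=interval[0],
            end=interval[1],
            name=_srna_name(prec_name, key[0], key[1]),
            seq=ext.seq[interval[0] : interval[1]],
            support_count=block.total_count,
        )
        used.add(id(block))

    # (i) expressed annotated matures
    for _, iv, arm in annotated:
        for block in blocks:
            if _matches(block, iv, oh):
                claim(("mir", arm), block, iv)

    # (ii) new miRNAs from star projection (only on arms with no annotation)
    annotated_arms = {arm for _, _, arm in annotated}
    star_by_arm: dict[str, tuple[int, int]] = {}
    for _, iv, _ in annotated:
        star = project_star(
            iv,
            fold_result,
            min_paired_frac=p.star_min_paired_frac,
            overhang=p.star_overhang,
            annotated=ann_intervals,
            max_annotated_overlap=p.star_max_annotated_overlap,
        )
        if star is None:
            continue
        star_arm = arm_of(star, fold_result)
        if star_arm in annotated_arms:
            continue
        star_by_arm.setdefault(star_arm, star)
    for arm, star in star_by_arm.items():
        for block in blocks:
            if id(block) in used:
                continue
            if _matches(block, star, oh):
                claim(("new_mir", arm), block, (block.start, block.end))

    # arm anchors for moR/loop geometry: defined miRs, else annotation, else star
    def anchor(arm: str) -> Optional[tuple[int, int]]:
        for klass in ("mir", "new_mir"):
            d = defs.get((klass, arm))
            if d is not None:
                return d.interval
        for _, iv, a in annotated:
            if a == arm:
                return iv
        return star_by_arm.get(arm)

    geometry = candidate_mor_geometry(
        ext, anchor("5p"), anchor("3p"), overlap_slack=p.overlap_slack
    )

    # (iii) moRNAs from blocks in the flanking windows
    for arm, window in (("5p", geometry.mor5p_window), ("3p", geometry.mor3p_window)):
        if window is None:
            continue
        for block in blocks:
            if id(block) in used:
                continue
            if _within(block, window) and block.end - block.start >= p.min_morna_len:
                claim(("mor", arm), block, (block.start, block.end))

    # (iv) loop sRNA
    if geometry.loop is not None:
        for block in blocks:
            if id(block) in used:
                continue
            if _within(block, geometry.loop):
                claim(("loop", "loop"), block, (block.start, block.end))

    out = sorted(defs.values(), key=lambda d: (CLASS_RANK[d.srna_class], ARM_RANK[d.arm]))
    return out


def mor_sequence_filter(
    mor_defs: Sequence[SrnaDefinition],
    mir_defs: Sequence[SrnaDefinition],
    mode: str = "conservative",
) -> list[SrnaDefinition]:
    """Drop moRNAs whose sequence is shared with any miR in the catalog.

    Conservative mode removes a moR when its sequence is a substring of any
    miR/new_mir sequence or vice versa (applied across all precursors);
    permissive mode keeps everything.
    """
    if mode == "permissive":
        return list(mor_defs)
    if mode != "conservative":
        raise ValueError("mode must be 'conservative' or 'permissive'")
    kept = []
    for mor in mor_defs:
        shared = any(mor.seq in mir.seq or mir.seq in mor.seq for mir in mir_defs)
        if not shared:
            kept.append(mor)
    return kept


def assign_alignment(
    aln: PrecursorAlignment,
    srnas: Sequence[SrnaDefinition],
    p: AssignParams,
) -> Optional[SrnaDefinition]:
    """Assign an alignment to the best-overlapping sRNA, or ``None``.

    Assignable iff each alignment end lies within ``allowed_overhang`` of the
    sRNA's corresponding end.  Ties on reciprocal overlap are broken by class
    precedence mir > new_mir > mor > loop, then 5p before 3p.
    """
    oh = p.allowed_overhang
    best: Optional[tuple[float, int, int, SrnaDefinition]] = None
    for s in srnas:
        if s.precursor_id != aln.precursor_id:
            continue
        if abs(aln.start - s.start) > oh or abs(aln.end - s.end) > oh:
            continue
        ov = min(aln.end, s.end) - max(aln.start, s.start)
        if ov <= 0:
            continue
        union = max(aln.end, s.end) - min(aln.start, s.start)
        recip = ov / union
        key = (-recip, CLASS_RANK[s.srna_class], ARM_RANK[s.arm])
        if best is None or key < (-best[0], best[1], best[2]):
            best = (recip, CLASS_RANK[s.srna_class], ARM_RANK[s.arm], s)
    return best[3] if best else None
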