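"""Extended precursors, secondary-structure folding, star-sequence projection
and candidate moRNA/loop geometry.

The built-in folder maximizes base pairs (Watson-Crick + G.U wobble, minimum
loop 3) by dynamic programming: only the pairing topology is consumed
downstream, so a thermodynamic folder is not required.  A pre-computed
dot-bracket can be supplied instead (external-fold mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .formats_io import GenomeRef, Mature, Precursor, revcomp

DEFAULT_FLANK = 30

# DNA alphabet internally; U is normalized to T on input.
_CAN_PAIR = {
    ("A", "T"), ("T", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "T"), ("T", "G"),
}

MIN_LOOP = 3  # no pair (i, j) with j - i < MIN_LOOP + 1


def can_pair(a: str, b: str) -> bool:
    return (a, b) in _CAN_PAIR


@dataclass
class ExtendedPrecursor:
    """Precursor sequence plus up to 30 nt of genomic flank on each side.

    ``seq`` is on the transcribed strand; local coordinate 0 is the
    transcript 5' end.  ``genomic_start`` anchors the extended slice on the
    + strand axis of ``chrom``.
    """

    id: str
    seq: str
    chrom: str
    strand: str
    genomic_start: int  # 0-based + strand start of the extended slice
    flank5: int
    flank3: int
    matures: dict[str, tuple[int, int]] = field(default_factory=dict)  # name -> local interval

    def __post_init__(self) -> None:
        if not (0 <= self.flank5 <= DEFAULT_FLANK and 0 <= self.flank3 <= DEFAULT_FLANK):
            raise ValueError("flanks must be within [0, 30]")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def genomic_end(self) -> int:
        return self.genomic_start + len(self.seq)

    @property
    def precursor_interval(self) -> tuple[int, int]:
        """The original (unextended) precursor in local coordinates."""
        return self.flank5, len(self.seq) - self.flank3

    def local_to_genomic(self, start: int, end: int) -> tuple[int, int]:
        if self.strand == "+":
            return self.genomic_start + start, self.genomic_start + end
        return self.genomic_end - end, self.genomic_end - start

    def genomic_to_local(self, start: int, end: int) -> tuple[int, int]:
        if self.strand == "+":
            return start - self.genomic_start, end - self.genomic_start
        return self.genomic_end - end, self.genomic_end - start


def extend_precursor(
    prec: Precursor,
    matures: Sequence[Mature],
    genome: GenomeRef,
    flank: int = DEFAULT_FLANK,
) -> ExtendedPrecursor:
    """Slice precursor +/- ``flank`` nt from the genome on the transcribed strand.

    Flanks are truncated at contig boundaries and the obtained lengths
    recorded.  Annotated matures are converted to extended-local coordinates.
    """
    if prec.chrom not in genome.sequences:
        raise KeyError(f"precursor {prec.id}: chromosome {prec.chrom!r} not in genome")
    chrom_len = len(genome.sequences[prec.chrom])
    gstart = max(0, prec.start - flank)
    gend = min(chrom_len, prec.end + flank)
    seq = genome.fetch(prec.chrom, gstart, gend, prec.strand)
    if prec.strand == "+":
        flank5, flank3 = prec.start - gstart, gend - prec.end
    else:
        flank5, flank3 = gend - prec.end, prec.start - gstart
    ext = ExtendedPrecursor(
        id=prec.id,
        seq=seq,
        chrom=prec.chrom,
        strand=prec.strand,
        genomic_start=gstart,
        flank5=flank5,
        flank3=flank3,
    )
    for m in matures:
        local = ext.genomic_to_local(m.start, m.end)
        ext.matures[m.name or m.id] = local
    return ext


@dataclass
class FoldResult:
    """Nested secondary structure: dot-bracket plus a pair table (-1 = unpaired)."""

    structure: str
    pairs: list[int]

    def __post_init__(self) -> None:
        n = len(self.structure)
        if len(self.pairs) != n:
            raise ValueError("pair table length != structure length")
        for i, j in enumerate(self.pairs):
            if j == -1:
                continue
            if not (0 <= j < n) or self.pairs[j] != i or i == j:
                raise ValueError(f"inconsistent pair table at {i}")
            if abs(i - j) < MIN_LOOP + 1:
                raise ValueError(f"pair ({i},{j}) violates minimum loop length {MIN_LOOP}")

    @property
    def n_pairs(self) -> int:
        return sum(1 for i, j in enumerate(self.pairs) if j > i)


def parse_dot_bracket(structure: str) -> list[int]:
    """Pair table from a dot-bracket string; raises on unbalanced brackets."""
    pairs = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[j], pairs[i] = i, j
        elif c != ".":
            raise ValueError(f"invalid character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def fold(sequence: str, structure: Optional[str] = None) -> FoldResult:
    """Fold a sequence, or validate a supplied dot-bracket against it.

    The built-in folder returns a maximum base-pair nested structure
    (Watson-Crick + G.U, minimum loop 3).  Ties are broken deterministically
    by the traceback order (prefer leaving i unpaired last, outermost pairing
    first), so identical inputs give identical structures.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    if structure is not None:
        if len(structure) != n:
            raise ValueError("structure length != sequence length")
        return FoldResult(structure=structure, pairs=parse_dot_bracket(structure))
    if n < 10:
        raise ValueError("sequence too short to fold (need >= 10 nt)")

    # Nussinov DP: best[i][j] = max pairs in seq[i..j] inclusive.
    best = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            score = best[i + 1][j]  # i unpaired
            for k in range(i + MIN_LOOP + 1, j + 1):
                if can_pair(seq[i], seq[k]):
                    inner = best[i + 1][k - 1] if k - 1 >= i + 1 else 0
                    right = best[k + 1][j] if k + 1 <= j else 0
                    cand = inner + 1 + right
                    if cand > score:
                        score = cand
            best[i][j] = score

    pairs = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < MIN_LOOP + 1:
            continue
        target = best[i][j]
        # prefer pairing i, widest span first, over leaving it unpaired
        paired = False
        for k in range(j, i + MIN_LOOP, -1):
            if can_pair(seq[i], seq[k]):
                inner = best[i + 1][k - 1] if k - 1 >= i + 1 else 0
                right = best[k + 1][j] if k + 1 <= j else 0
                if inner + 1 + right == target:
                    pairs[i], pairs[k] = k, i
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))

    db = "".join("." if p == -1 else ("(" if p > i else ")") for i, p in enumerate(pairs))
    return FoldResult(structure=db, pairs=pairs)


def project_star(
    mature: tuple[int, int],
    fold_result: FoldResult,
    min_paired_frac: float = 0.6,
    overhang: int = 2,
    annotated: Sequence[tuple[int, int]] = (),
    max_annotated_overlap: int = 3,
) -> Optional[tuple[int, int]]:
    """Project the complementary (star) interval of a mature miRNA.

    The star spans the pairing partners of the mature's paired positions,
    shifted by the canonical 2-nt 3' overhang of the processed duplex.
    Returns ``None`` when fewer than ``min_paired_frac`` of mature positions
    are paired (no hairpin support) or when the star would overlap an
    annotated mature by more than ``max_annotated_overlap`` nt.
    """
    s, e = mature
    n = len(fold_result.pairs)
    partners = [fold_result.pairs[i] for i in range(s, e) if fold_result.pairs[i] != -1]
    if not partners or len(partners) / (e - s) < min_paired_frac:
        return None
    mn, mx = min(partners), max(partners)
    star = (max(0, mn + overhang), min(n, mx + 1 + overhang))
    for a_s, a_e in annotated:
        ov = min(star[1], a_e) - max(star[0], a_s)
        if ov > max_annotated_overlap:
            return None
    return star


@dataclass
class MorGeometry:
    """Candidate windows for moRNAs and the loop interval, extended-local."""

    mor5p_window: Optional[tuple[int, int]]
    mor3p_window: Optional[tuple[int, int]]
    loop: Optional[tuple[int, int]]


def candidate_mor_geometry(
    ext: ExtendedPrecursor,
    mir5p: Optional[tuple[int, int]],
    mir3p: Optional[tuple[int, int]],
    overlap_slack: int = 3,
) -> MorGeometry:
    """MoRNA windows adjacent to the defined miR arms, plus the loop interval.

    moR-5p window runs from the extended 5' end to just past the 5p miR
    start; moR-3p from just before the 3p miR end to the extended 3' end
    (``overlap_slack`` terminal bases may be shared with the adjacent miR).
    The loop lies strictly between the two arms when both are defined.
    """
    n = len(ext.seq)
    mor5p = (0, min(n, mir5p[0] + overlap_slack)) if mir5p is not None else None
    mor3p = (max(0, mir3p[1] - overlap_slack), n) if mir3p is not None else None
    loop = None
    if mir5p is not None and mir3p is not None and mir5p[1] < mir3p[0]:
        loop = (mir5p[1], mir3p[0])
    return MorGeometry(mor5p_window=mor5p, mor3p_window=mor3p, loop=loop)


def arm_of(interval: tuple[int, int], fold_result: FoldResult) -> str:
    """Classify an interval as 5p or 3p relative to the hairpin loop.

    The hinge is taken from the innermost pair of the main stem; when the
    structure has no pairs the sequence midpoint is used.
    """
    hinge = len(fold_result.pairs) / 2.0
    candidates = [(i, j) for i, j in enumerate(fold_result.pairs) if j > i]
    if candidates:
        i, j = max(candidates, key=lambda ij: ij[0])
        hinge = (i + j) / 2.0
    center = (interval[0] + interval[1]) / 2.0
    return "5p" if center <= hinge else "3p"
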