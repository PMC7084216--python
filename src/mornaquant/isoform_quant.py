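"""Isoform classification of assigned alignments and expression matrices.

Eight mutually exclusive labels: canonical plus seven variant types.  The
mismatch classes take precedence over the length classes when both occur;
end offsets and mismatch positions are still emitted so no detail is lost.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .assign import PrecursorAlignment, SrnaDefinition

ISOFORM_TYPES = (
    "canonical",
    "mm1",
    "mm2_3p",
    "short5p",
    "short3p",
    "long5p",
    "long3p",
    "len_both",
)


@dataclass(frozen=True)
class IsoformRecord:
    srna: str
    precursor_id: str
    srna_class: str
    isoform_type: str
    offset5: int
    offset3: int
    mm_positions: tuple[int, ...]
    sequence: str
    count: int
    cross_mapped: bool = False

    def __post_init__(self) -> None:
        if self.isoform_type not in ISOFORM_TYPES:
            raise ValueError(f"unknown isoform type {self.isoform_type!r}")


def classify_isoform(aln: PrecursorAlignment, canonical: SrnaDefinition) -> str:
    """Label an assigned alignment relative to its canonical sRNA.

    1 mismatch -> mm1; 2 mismatches (already 3'-filtered upstream) ->
    mm2_3p; otherwise the end offsets decide: 5'-only deviation ->
    short5p/long5p, 3'-only -> short3p/long3p, both ends -> len_both, none
    -> canonical.
    """
    if aln.n_mismatches == 1:
        return "mm1"
    if aln.n_mismatches == 2:
        return "mm2_3p"
    d5 = aln.start - canonical.start
    d3 = aln.end - canonical.end
    if d5 == 0 and d3 == 0:
        return "canonical"
    if d5 != 0 and d3 != 0:
        return "len_both"
    if d5 != 0:
        return "short5p" if d5 > 0 else "long5p"
    return "short3p" if d3 < 0 else "long3p"


def make_record(
    aln: PrecursorAlignment,
    srna: SrnaDefinition,
    cross_mapped: bool = False,
) -> IsoformRecord:
    return IsoformRecord(
        srna=srna.name,
        precursor_id=srna.precursor_id,
        srna_class=srna.srna_class,
        isoform_type=classify_isoform(aln, srna),
        offset5=aln.start - srna.start,
        offset3=aln.end - srna.end,
        mm_positions=aln.mismatches,
        sequence=aln.tag.seq,
        count=aln.tag.count,
        cross_mapped=cross_mapped,
    )


def quantify(
    assignments: Mapping[str, Iterable[IsoformRecord]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-sample isoform records into tables.

    Returns ``(isoforms, counts)``: the long per-isoform table and the
    per-sRNA count matrix (rows sRNA, a 'class' column flagging loops for
    optional downstream removal, one integer column per sample).
    """
    iso_rows = []
    classes: dict[str, str] = {}
    for sample, records in assignments.items():
        for r in records:
            classes[r.srna] = r.srna_class
            iso_rows.append(
                {
                    "sample": sample,
                    "precursor": r.precursor_id,
                    "srna": r.srna,
                    "class": r.srna_class,
                    "isoform_type": r.isoform_type,
                    "offset5": r.offset5,
                    "offset3": r.offset3,
                    "mm_positions": ",".join(map(str, r.mm_positions)),
                    "sequence": r.sequence,
                    "count": r.count,
                    "cross_mapped": r.cross_mapped,
                }
            )
    iso_cols = [
        "sample",
        "precursor",
        "srna",
        "class",
        "isoform_type",
        "offset5",
        "offset3",
        "mm_positions",
        "sequence",
        "count",
        "cross_mapped",
    ]
    isoforms = pd.DataFrame(iso_rows, columns=iso_cols)
    samples = list(assignments.keys())
    if isoforms.empty:
        counts = pd.DataFrame(columns=["class"] + samples)
        counts.index.name = "srna"
        return isoforms, counts
    pivot = (
        isoforms.groupby(["srna", "sample"])["count"].sum().unstack(fill_value=0)
    )
    pivot = pivot.reindex(columns=samples, fill_value=0).astype(int)
    pivot.insert(0, "class", [classes[s] for s in pivot.index])
    pivot.index.name = "srna"
    return isoforms, pivot


def cpm(counts: pd.DataFrame, include_loops: bool = False) -> pd.DataFrame:
    """Counts-per-million normalization of a count matrix.

    When ``include_loops`` is false, loop rows are removed before totals are
    computed, renormalizing the remaining rows upward.  Each sample column
    then sums to 1e6 (unless all-zero, which is an error).
    """
    matrix = counts if include_loops else counts[counts["class"] != "loop"]
    samples = [c for c in matrix.columns if c != "class"]
    values = matrix[samples].astype(float)
    totals = values.sum(axis=0)
    if (totals == 0).any():
        zero = [s for s in samples if totals[s] == 0]
        raise ValueError(f"zero total count in sample(s): {zero}")
    out = values / totals * 1e6
    out.insert(0, "class", matrix["class"])
    return out


_MIR_PREFIX = re.compile(r"mir-", re.IGNORECASE)


def name_srna(precursor_name: str, srna_class: str, arm: str) -> str:
    """Build the display name of an sRNA from its precursor name.

    The species and 'mir-' prefix are stripped: ('hsa-mir-421', 'mor',
    '5p') -> 'moR-421-5p'; loops carry no arm: 'loop-421'.
    """
    m = _MIR_PREFIX.search(precursor_name)
    core = precursor_name[m.end() :] if m else precursor_name
    if srna_class == "loop":
        return f"loop-{core}"
    prefix = {"mir": "miR", "new_mir": "miR", "mor": "moR"}[srna_class]
    return f"{prefix}-{core}-{arm}"
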