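"""Standard-format I/O and the coordinate convention shared by the whole package.

All internal intervals are 0-based, half-open, on the transcribed (5'->3')
strand of the feature they describe.  GFF3 input/output is the single place
where conversion to/from 1-based inclusive genomic coordinates happens.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastqParseError(ValueError):
    """Malformed FASTQ record; message carries the offending line number."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier, uppercase DNA and Phred+33 qualities."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual]


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream 4-line FASTQ records (plain or gzip).

    Raises :class:`FastqParseError` naming the 1-based line number of the
    first malformed line.
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(f"line {lineno}: expected '@' header, got {header[:20]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FastqParseError(f"line {lineno}: truncated record")
            if not plus.startswith("+"):
                raise FastqParseError(f"line {lineno + 2}: expected '+' separator")
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"line {lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            if len(seq) < 1:
                raise FastqParseError(f"line {lineno + 1}: empty sequence")
            lineno += 3
            yield ReadRecord(id=header[1:].split()[0], seq=seq.upper(), qual=qual)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


@dataclass
class GenomeRef:
    """Reference genome held in memory as a name -> sequence map."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {name!r}")

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.sequences[chrom][start:end]
        return revcomp(seq) if strand == "-" else seq

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeRef":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate FASTA record name {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
        return cls(seqs)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class Precursor:
    id: str
    chrom: str
    start: int  # 0-based half-open genomic
    end: int
    strand: str
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"precursor {self.id}: bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"precursor {self.id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class Mature:
    id: str
    parent: str  # precursor id
    chrom: str
    start: int
    end: int
    strand: str
    name: str = ""


@dataclass
class MirAnnotation:
    """Precursor/mature miRNA annotation with resolved parent linkage."""

    precursors: list[Precursor] = field(default_factory=list)
    matures: list[Mature] = field(default_factory=list)

    def matures_of(self, precursor_id: str) -> list[Mature]:
        return [m for m in self.matures if m.parent == precursor_id]

    def extend(self, other: "MirAnnotation") -> None:
        self.precursors.extend(other.precursors)
        self.matures.extend(other.matures)


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_mir_gff3(path: str | Path) -> MirAnnotation:
    """Parse a miRBase-dialect GFF3 annotation.

    Recognizes ``miRNA_primary_transcript`` and ``miRNA`` features.  1-based
    inclusive coordinates are converted to the internal 0-based half-open
    convention.  Mature->precursor linkage uses ``Derives_from`` when present
    and falls back to same-strand containment; a mature contained in several
    precursors is linked to all of them.  Matures with no resolvable parent
    are dropped with a warning.
    """
    precursors: list[Precursor] = []
    raw_matures: list[tuple[str, str, str, int, int, str, str | None]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                continue
            chrom, _, ftype, start1, end1, _, strand, _, attr_text = fields
            if ftype not in ("miRNA_primary_transcript", "miRNA"):
                continue
            attrs = _parse_gff3_attributes(attr_text)
            ident = attrs.get("ID", "") or attrs.get("Name", "")
            name = attrs.get("Name", "") or ident
            start = int(start1) - 1
            end = int(end1)
            if ftype == "miRNA_primary_transcript":
                precursors.append(Precursor(ident, chrom, start, end, strand, name=name))
            else:
                raw_matures.append(
                    (ident, name, chrom, start, end, strand, attrs.get("Derives_from"))
                )

    by_id = {p.id: p for p in precursors}
    by_name = {p.name: p for p in precursors}
    matures: list[Mature] = []
    for ident, name, chrom, start, end, strand, derives in raw_matures:
        parents: list[Precursor] = []
        if derives and derives in by_id:
            parents = [by_id[derives]]
        elif derives and derives in by_name:
            parents = [by_name[derives]]
        else:
            parents = [
                p
                for p in precursors
                if p.chrom == chrom and p.strand == strand and p.start <= start and end <= p.end
            ]
        if not parents:
            log.warning("mature %s (%s) has no resolvable parent precursor; dropped", ident, name)
            continue
        for p in parents:
            matures.append(Mature(ident, p.id, chrom, start, end, strand, name=name))
    return MirAnnotation(precursors=precursors, matures=matures)


def write_mir_gff3(annotation: MirAnnotation, path: str | Path, source: str = "mornaquant") -> None:
    """Write annotation back out in the miRBase GFF3 dialect (1-based inclusive)."""
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for p in annotation.precursors:
            attrs = f"ID={p.id};Name={p.name or p.id}"
            fh.write(
                f"{p.chrom}\t{source}\tmiRNA_primary_transcript\t{p.start + 1}\t{p.end}\t."
                f"\t{p.strand}\t.\t{attrs}\n"
            )
            for m in annotation.matures_of(p.id):
                attrs = f"ID={m.id};Name={m.name or m.id};Derives_from={p.id}"
                fh.write(
                    f"{m.chrom}\t{source}\tmiRNA\t{m.start + 1}\t{m.end}\t."
                    f"\t{m.strand}\t.\t{attrs}\n"
                )


@dataclass(frozen=True)
class CatalogEntry:
    """One predicted/confirmed sRNA with its genomic placement."""

    name: str
    srna_class: str  # mir | new_mir | mor | loop
    precursor_id: str
    chrom: str
    start: int  # 0-based half-open genomic
    end: int
    strand: str


@dataclass
class RunResult:
    """Everything a pipeline run produces, ready for serialization."""

    samples: list[str]
    catalog: list[CatalogEntry]
    isoforms: "object"  # pandas.DataFrame
    counts: "object"  # pandas.DataFrame indexed by srna, 'class' column + one per sample
    unassigned: "object"  # pandas.DataFrame
    logs: dict = field(default_factory=dict)


ISOFORM_COLUMNS = [
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

UNASSIGNED_COLUMNS = ["sample", "sequence", "count", "reason"]


def write_catalog_gff3(catalog: list[CatalogEntry], precursors: list[Precursor], path: str | Path) -> None:
    """Emit the sRNA catalog as GFF3: precursor rows plus derived sRNA rows."""
    with_defs = {c.precursor_id for c in catalog}
    with open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for p in precursors:
            if p.id not in with_defs:
                continue
            fh.write(
                f"{p.chrom}\tmornaquant\tmiRNA_primary_transcript\t{p.start + 1}\t{p.end}\t."
                f"\t{p.strand}\t.\tID={p.id};Name={p.name or p.id}\n"
            )
            for c in catalog:
                if c.precursor_id != p.id:
                    continue
                fh.write(
                    f"{c.chrom}\tmornaquant\tmiRNA\t{c.start + 1}\t{c.end}\t.\t{c.strand}\t.\t"
                    f"ID={c.name};Name={c.name};Derives_from={p.id};class={c.srna_class}\n"
                )


def write_outputs(result: RunResult, outdir: str | Path, precursors: list[Precursor] | None = None) -> dict[str, Path]:
    """Write catalog GFF3, isoform TSV, count matrix TSV, unassigned TSV, run log.

    Returns a map output-name -> path.  With zero predictions the tabular
    files still carry their header rows.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "catalog": outdir / "catalog.gff3",
        "isoforms": outdir / "isoforms.tsv",
        "counts": outdir / "counts.tsv",
        "unassigned": outdir / "unassigned.tsv",
        "log": outdir / "run_log.json",
    }
    write_catalog_gff3(result.catalog, precursors or [], paths["catalog"])
    result.isoforms.to_csv(paths["isoforms"], sep="\t", index=False)
    result.counts.to_csv(paths["counts"], sep="\t", index=True, index_label="srna")
    result.unassigned.to_csv(paths["unassigned"], sep="\t", index=False)
    with open(paths["log"], "wt") as fh:
        json.dump(result.logs, fh, indent=2, sort_keys=True)
    return paths
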