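"""Seeded generator of synthetic genomes, hairpin precursors, annotations and
FASTQ reads with planted miR/star/moR/loop truth.

Everything is driven by one ``random.Random`` stream, so a fixed seed yields
byte-identical output files.  Reads are built from truth — variation is
planted, never stochastic noise.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .formats_io import (
    GenomeRef,
    Mature,
    MirAnnotation,
    Precursor,
    ReadRecord,
    revcomp,
)
from .hairpin import ExtendedPrecursor, extend_precursor
from .isoform_quant import name_srna

# Alphabet choices that keep the designed stem the unique pairing optimum:
# 5' arms use A/G (3' arms are then C/T), loops and background are A/C-rich,
# so spurious base pairs competing with the stem are rare.
_ARM5_BASES = "AG"
_LOOP_BASES = "AC"
_BG_WEIGHTS = {"A": 0.45, "C": 0.45, "G": 0.05, "T": 0.05}

DEFAULT_COUNTS = {"mir": 120, "new_mir": 80, "mor5p": 40, "mor3p": 30, "loop": 25}


def _rng(seed: int | random.Random) -> random.Random:
    return seed if isinstance(seed, random.Random) else random.Random(seed)


@dataclass
class HairpinDesign:
    """A synthetic precursor: perfect (optionally bulged) stem-loop with one
    annotated mature, in precursor-local coordinates."""

    name: str
    seq: str
    mature_local: tuple[int, int]
    mature_arm: str
    stem_len: int
    loop_len: int
    mir_len: int
    bulges: int = 0


def make_hairpin(
    seed: int | random.Random,
    stem_len: int = 25,
    loop_len: int = 18,
    mir_len: int = 22,
    bulges: int = 0,
    mature_arm: str = "5p",
    name: str = "sim-mir-1",
) -> HairpinDesign:
    """Build a stem-loop precursor with the mature placed flush to the loop.

    The 3' arm is the exact reverse complement of the 5' arm; ``bulges``
    unpaired bases are inserted into the arm opposite the mature.
    """
    if not (stem_len >= mir_len >= 16):
        raise ValueError("need stem_len >= mir_len >= 16")
    if loop_len < 4:
        raise ValueError("need loop_len >= 4")
    rng = _rng(seed)
    arm5 = "".join(rng.choice(_ARM5_BASES) for _ in range(stem_len))
    loop = "".join(rng.choice(_LOOP_BASES) for _ in range(loop_len))
    arm3 = revcomp(arm5)
    if bulges:
        opposite_is_3p = mature_arm == "5p"
        target = list(arm3 if opposite_is_3p else arm5)
        for _ in range(bulges):
            pos = rng.randrange(2, len(target) - 2)
            target.insert(pos, rng.choice("AC"))
        if opposite_is_3p:
            arm3 = "".join(target)
        else:
            arm5 = "".join(target)
    seq = arm5 + loop + arm3
    if mature_arm == "5p":
        mature = (len(arm5) - mir_len, len(arm5))
    elif mature_arm == "3p":
        mature = (len(arm5) + len(loop), len(arm5) + len(loop) + mir_len)
    else:
        raise ValueError("mature_arm must be '5p' or '3p'")
    return HairpinDesign(name, seq, mature, mature_arm, stem_len, loop_len, mir_len, bulges)


@dataclass(frozen=True)
class Placement:
    chrom: str
    start: int  # 0-based half-open genomic, + strand axis
    end: int
    strand: str


def _random_background(rng: random.Random, n: int, weights: Mapping[str, float]) -> list[str]:
    bases = list(weights.keys())
    w = [weights[b] for b in bases]
    return rng.choices(bases, weights=w, k=n)


def make_genome(
    designs: Sequence[HairpinDesign],
    seed: int | random.Random,
    genome_len: int = 20000,
    chrom: str = "chrSim",
    strands: Optional[Sequence[str]] = None,
    repeat_spec: Optional[tuple[str, int]] = None,
    margin: int = 80,
    bg_weights: Optional[Mapping[str, float]] = None,
) -> tuple[GenomeRef, MirAnnotation, dict[str, Placement]]:
    """Embed precursors at random non-overlapping loci in a random background.

    ``repeat_spec=(seq, k)`` additionally plants ``seq`` at ``k`` intergenic
    loci to exercise the multi-mapping rule.  Returns the genome, a
    miRBase-dialect annotation, and the placement of each design.
    """
    rng = _rng(seed)
    background = _random_background(rng, genome_len, bg_weights or _BG_WEIGHTS)
    if strands is None:
        strands = ["+" if i % 2 == 0 else "-" for i in range(len(designs))]

    occupied: list[tuple[int, int]] = []

    def reserve(length: int) -> int:
        for _ in range(10000):
            start = rng.randrange(margin, genome_len - length - margin)
            if not any(start < e + margin and s - margin < start + length for s, e in occupied):
                occupied.append((start, start + length))
                return start
        raise RuntimeError("could not place feature; genome too small")

    placements: dict[str, Placement] = {}
    precursors: list[Precursor] = []
    matures: list[Mature] = []
    for i, (design, strand) in enumerate(zip(designs, strands)):
        L = len(design.seq)
        start = reserve(L)
        plus_seq = design.seq if strand == "+" else revcomp(design.seq)
        background[start : start + L] = list(plus_seq)
        placements[design.name] = Placement(chrom, start, start + L, strand)
        prec_id = f"SIMPREC{i + 1}"
        precursors.append(Precursor(prec_id, chrom, start, start + L, strand, name=design.name))
        a, b = design.mature_local
        if strand == "+":
            g = (start + a, start + b)
        else:
            g = (start + L - b, start + L - a)
        matures.append(
            Mature(
                f"SIMMAT{i + 1}",
                prec_id,
                chrom,
                g[0],
                g[1],
                strand,
                name=f"{design.name}-{design.mature_arm}",
            )
        )

    if repeat_spec is not None:
        seq, k = repeat_spec
        for _ in range(k):
            start = reserve(len(seq))
            background[start : start + len(seq)] = list(seq)

    genome = GenomeRef({chrom: "".join(background)})
    return genome, MirAnnotation(precursors=precursors, matures=matures), placements


@dataclass(frozen=True)
class PlantedSrna:
    """Ground truth for one planted sRNA, in extended-precursor coordinates."""

    name: str
    precursor_id: str
    precursor_name: str
    srna_class: str  # mir | new_mir | mor | loop
    arm: str
    start: int
    end: int
    seq: str
    count: int
    ctx5: str = ""  # up to 4 extended-precursor bases 5' of the interval
    ctx3: str = ""  # up to 4 bases 3' of the interval


def derive_truth(
    design: HairpinDesign,
    ext: ExtendedPrecursor,
    counts: Mapping[str, int],
    mor_len: int = 20,
) -> list[PlantedSrna]:
    """Analytic truth intervals for a perfect-stem design (bulges == 0).

    The star interval is the pairing-partner span of the mature shifted by
    the 2-nt 3' overhang of the processed duplex; moRNAs sit immediately
    outside the two miR arms and the loop sRNA spans the region between them.
    """
    if design.bulges:
        raise ValueError("analytic truth requires a perfect stem (bulges=0)")
    f5 = ext.flank5
    K = 2 * design.stem_len + design.loop_len - 1  # last precursor-local index
    s, e = design.mature_local
    star = (K - e + 3, K - s + 3)
    mature_ext = (f5 + s, f5 + e)
    star_ext = (f5 + star[0], f5 + star[1])
    if design.mature_arm == "5p":
        mir5p, mir3p = mature_ext, star_ext
    else:
        mir5p, mir3p = star_ext, mature_ext
    planted: list[PlantedSrna] = []

    def add(key: str, srna_class: str, arm: str, interval: tuple[int, int]) -> None:
        if key not in counts:
            return
        a, b = interval
        if not (0 <= a < b <= len(ext.seq)):
            raise ValueError(f"planted {key} interval out of extended bounds: {interval}")
        planted.append(
            PlantedSrna(
                name=name_srna(design.name, srna_class, arm),
                precursor_id=ext.id,
                precursor_name=design.name,
                srna_class=srna_class,
                arm=arm,
                start=a,
                end=b,
                seq=ext.seq[a:b],
                count=counts[key],
                ctx5=ext.seq[max(0, a - 4) : a],
                ctx3=ext.seq[b : b + 4],
            )
        )

    add("mir", "mir", design.mature_arm, mature_ext)
    add("new_mir", "new_mir", "3p" if design.mature_arm == "5p" else "5p", star_ext)
    add("mor5p", "mor", "5p", (mir5p[0] - mor_len, mir5p[0]))
    add("mor3p", "mor", "3p", (mir3p[1], mir3p[1] + mor_len))
    add("loop", "loop", "loop", (mir5p[1], mir3p[0]))
    return planted


def simulate_reads(
    planted: Sequence[PlantedSrna],
    seed: int | random.Random,
    adapter: Optional[str] = None,
    isoform_mix: Optional[Mapping[str, float]] = None,
    qual_char: str = "I",
    lowq_fraction: float = 0.0,
) -> tuple[list[ReadRecord], list[dict]]:
    """Emit reads for each planted sRNA according to an isoform mix.

    Supported mix labels: ``canonical``, ``short5p``, ``short3p``,
    ``long5p``, ``long3p``, ``mm1``, ``mm2_3p``.  ``mm2_3p`` reads carry two
    3' bases differing from the templated continuation, so they align with
    two mismatches at the last two read positions.  ``lowq_fraction`` of each
    sRNA's reads get three Phred-10 bases, which must fail quality
    filtering.  Returns the reads and a truth manifest (one dict per read).
    """
    rng = _rng(seed)
    mix = dict(isoform_mix or {"canonical": 1.0})
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("isoform_mix fractions must sum to 1")
    reads: list[ReadRecord] = []
    manifest: list[dict] = []
    idx = 0

    def variant_seq(p: PlantedSrna, label: str) -> str:
        if label == "canonical":
            return p.seq
        if label == "short3p":
            return p.seq[:-1]
        if label == "short5p":
            return p.seq[1:]
        if label == "long3p":
            if not p.ctx3:
                raise ValueError(f"no 3' context for {p.name}")
            return p.seq + p.ctx3[0]
        if label == "long5p":
            if not p.ctx5:
                raise ValueError(f"no 5' context for {p.name}")
            return p.ctx5[-1] + p.seq
        if label == "mm1":
            pos = len(p.seq) // 2
            alt = next(b for b in "ACGT" if b != p.seq[pos])
            return p.seq[:pos] + alt + p.seq[pos + 1 :]
        if label == "mm2_3p":
            if len(p.ctx3) < 2:
                raise ValueError(f"no 3' context for {p.name}")
            b1 = next(b for b in "ACGT" if b != p.ctx3[0])
            b2 = next(b for b in "ACGT" if b != p.ctx3[1])
            return p.seq + b1 + b2
        raise ValueError(f"unknown isoform mix label {label!r}")

    for p in planted:
        n_by_label: dict[str, int] = {}
        assigned = 0
        labels = [l for l in mix if l != "canonical"]
        for label in labels:
            n = int(round(mix[label] * p.count))
            n_by_label[label] = n
            assigned += n
        n_by_label["canonical"] = p.count - assigned if "canonical" in mix else 0
        if n_by_label["canonical"] < 0:
            raise ValueError("isoform_mix allocates more reads than the planted count")
        n_lowq = int(round(lowq_fraction * p.count))
        for label in ["canonical"] + labels:
            for _ in range(n_by_label.get(label, 0)):
                idx += 1
                insert = variant_seq(p, label)
                seq = insert + (adapter or "")
                qual = list(qual_char * len(seq))
                is_lowq = n_lowq > 0
                if is_lowq:
                    n_lowq -= 1
                    for pos in rng.sample(range(len(insert)), k=min(3, len(insert))):
                        qual[pos] = "+"  # Phred 10
                reads.append(ReadRecord(f"sim{idx}", seq, "".join(qual)))
                manifest.append(
                    {
                        "read_id": f"sim{idx}",
                        "srna": p.name,
                        "label": "lowq" if is_lowq else label,
                        "insert": insert,
                    }
                )
    return reads, manifest


def true_extended_structure(design: HairpinDesign, ext: ExtendedPrecursor) -> str:
    """Designed dot-bracket of the extended precursor (perfect stem only).

    Flanks and loop are unpaired; arm position i pairs its mirror position.
    Used as external-fold input so star projection sees the planted geometry,
    the way the real pipeline consumes a thermodynamic folder's output.
    """
    if design.bulges:
        raise ValueError("true structure is defined only for perfect stems")
    n = len(ext.seq)
    chars = ["."] * n
    f5 = ext.flank5
    for i in range(design.stem_len):
        chars[f5 + i] = "("
        chars[f5 + 2 * design.stem_len + design.loop_len - 1 - i] = ")"
    return "".join(chars)


@dataclass
class SimBundle:
    """A complete synthetic dataset plus its planted truth."""

    seed: int
    genome: GenomeRef
    annotation: MirAnnotation
    designs: list[HairpinDesign]
    placements: dict[str, Placement]
    planted: list[PlantedSrna]
    reads: list[ReadRecord]
    manifest: list[dict] = field(default_factory=list)
    adapter: Optional[str] = None
    structures: dict[str, str] = field(default_factory=dict)  # precursor id -> dot-bracket


def simulate_dataset(
    seed: int,
    n_precursors: int = 5,
    counts: Optional[Mapping[str, int]] = None,
    adapter: Optional[str] = "TGGAATTCTCGGGTGCCAAGG",
    isoform_mix: Optional[Mapping[str, float]] = None,
    genome_len: int = 20000,
    stem_len: int = 25,
    loop_len: int = 22,
    mir_len: int = 22,
    mor_len: int = 20,
    repeat_spec: Optional[tuple[str, int]] = None,
    lowq_fraction: float = 0.0,
) -> SimBundle:
    """One-call synthetic dataset: hairpins, genome, annotation, reads, truth."""
    rng = random.Random(seed)
    counts = dict(counts or DEFAULT_COUNTS)
    designs = [
        make_hairpin(
            rng,
            stem_len=stem_len,
            loop_len=loop_len,
            mir_len=mir_len,
            mature_arm="5p" if i % 2 == 0 else "3p",
            name=f"sim-mir-{i + 1}",
        )
        for i in range(n_precursors)
    ]
    genome, annotation, placements = make_genome(
        designs, rng, genome_len=genome_len, repeat_spec=repeat_spec
    )
    planted: list[PlantedSrna] = []
    structures: dict[str, str] = {}
    mat_by_parent = {p.id: annotation.matures_of(p.id) for p in annotation.precursors}
    for design, prec in zip(designs, annotation.precursors):
        ext = extend_precursor(prec, mat_by_parent[prec.id], genome)
        planted.extend(derive_truth(design, ext, counts, mor_len=mor_len))
        structures[prec.id] = true_extended_structure(design, ext)
    reads, manifest = simulate_reads(
        planted, rng, adapter=adapter, isoform_mix=isoform_mix, lowq_fraction=lowq_fraction
    )
    return SimBundle(
        seed=seed,
        genome=genome,
        annotation=annotation,
        designs=designs,
        placements=placements,
        planted=planted,
        reads=reads,
        manifest=manifest,
        adapter=adapter,
        structures=structures,
    )


def write_bundle(bundle: SimBundle, outdir) -> dict:
    """Serialize a bundle to FASTA/GFF3/FASTQ plus a truth manifest TSV."""
    from pathlib import Path

    from .formats_io import write_fasta, write_fastq, write_mir_gff3

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.gff3",
        "reads": outdir / "reads.fastq",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "read_manifest.tsv",
        "structures": outdir / "fold_structures.tsv",
    }
    write_fasta(bundle.genome.sequences, paths["genome"])
    write_mir_gff3(bundle.annotation, paths["annotation"])
    write_fastq(bundle.reads, paths["reads"])
    with open(paths["truth"], "wt") as fh:
        fh.write("srna\tprecursor\tclass\tarm\tstart\tend\tsequence\tcount\n")
        for p in bundle.planted:
            fh.write(
                f"{p.name}\t{p.precursor_id}\t{p.srna_class}\t{p.arm}\t{p.start}\t{p.end}"
                f"\t{p.seq}\t{p.count}\n"
            )
    with open(paths["structures"], "wt") as fh:
        for prec_id, structure in bundle.structures.items():
            fh.write(f"{prec_id}\t{structure}\n")
    with open(paths["manifest"], "wt") as fh:
        fh.write("read_id\tsrna\tlabel\tinsert\n")
        for row in bundle.manifest:
            fh.write(f"{row['read_id']}\t{row['srna']}\t{row['label']}\t{row['insert']}\n")
    return paths
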