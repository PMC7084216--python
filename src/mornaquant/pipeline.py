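"""Per-sample orchestration of the full pipeline:
preprocess -> genome filter -> hairpin -> assign -> isoform quantification."""

from __future__ import annotations

import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import assign as assign_mod
from . import genome_filter, hairpin, isoform_quant, preprocess
from .formats_io import (
    CatalogEntry,
    GenomeRef,
    MirAnnotation,
    RunResult,
    read_fastq,
    read_mir_gff3,
    write_outputs,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs.

    Parameter names mirror the published configuration keys (MIN_COUNT,
    MAX_LEN_FILTER, MEAN_QUAL_FILTER, MIN_MORNA_LEN, MORFILTER,
    ALLOWED_OVERHANG, NOADAPTER) via :func:`from_config_keys`.
    """

    samples: dict[str, str] = field(default_factory=dict)
    genome: str = ""
    annotation: str = ""
    extra_precursors: Optional[str] = None
    fold_structures: Optional[str] = None  # external-fold TSV (id, dot-bracket)
    outdir: str = "mornaquant_out"
    adapter: Optional[str] = None
    noadapter: bool = False
    min_len: int = 18
    max_len: int = 30
    mean_qual: float = 30.0
    min_count: int = 10
    max_outside_loci: int = 5
    max_hits_enumerated: int = 50
    allowed_overhang: int = 3
    min_morna_len: int = 16
    morfilter: str = "conservative"
    threads: int = 1
    seed: int = 0

    CONFIG_KEY_MAP = {
        "GENOME": "genome",
        "ANNOTATION": "annotation",
        "EXTRA_PRECURSORS": "extra_precursors",
        "FOLD_STRUCTURES": "fold_structures",
        "OUTPUT_DIR": "outdir",
        "ADAPTER": "adapter",
        "NOADAPTER": "noadapter",
        "MIN_LEN": "min_len",
        "MAX_LEN_FILTER": "max_len",
        "MEAN_QUAL_FILTER": "mean_qual",
        "MIN_COUNT": "min_count",
        "MAX_OUTSIDE_LOCI": "max_outside_loci",
        "MIN_MORNA_LEN": "min_morna_len",
        "MORFILTER": "morfilter",
        "ALLOWED_OVERHANG": "allowed_overhang",
        "THREADS": "threads",
        "SEED": "seed",
    }

    @classmethod
    def from_config_keys(cls, keys: dict[str, str], samples: dict[str, str]) -> "RunConfig":
        cfg = cls(samples=dict(samples))
        for key, raw in keys.items():
            attr = cls.CONFIG_KEY_MAP.get(key.upper())
            if attr is None:
                raise KeyError(f"unknown configuration key {key!r}")
            current = getattr(cfg, attr)
            if attr == "noadapter":
                value: object = raw.strip().lower() in ("true", "1", "yes")
            elif isinstance(current, bool):
                value = raw.strip().lower() in ("true", "1", "yes")
            elif isinstance(current, int):
                value = int(raw)
            elif isinstance(current, float):
                value = float(raw)
            else:
                value = raw.strip() or None
            setattr(cfg, attr, value)
        return cfg

    def preprocess_params(self) -> preprocess.PreprocessParams:
        return preprocess.PreprocessParams(
            adapter=self.adapter,
            min_len=self.min_len,
            max_len=self.max_len,
            mean_qual=self.mean_qual,
            min_count=self.min_count,
        )

    def multimap_params(self) -> genome_filter.MultimapParams:
        return genome_filter.MultimapParams(
            max_hits_enumerated=self.max_hits_enumerated,
            max_outside_loci=self.max_outside_loci,
        )

    def assign_params(self) -> assign_mod.AssignParams:
        return assign_mod.AssignParams(
            allowed_overhang=self.allowed_overhang,
            min_morna_len=self.min_morna_len,
            morfilter=self.morfilter,
        )


def validate_config(cfg: RunConfig) -> list[str]:
    """Check file existence and parameter ranges; returns violations."""
    violations: list[str] = []
    if not cfg.samples:
        violations.append("no samples configured")
    for name, path in cfg.samples.items():
        if not Path(path).is_file():
            violations.append(f"sample {name}: FASTQ not found: {path}")
    if not cfg.genome or not Path(cfg.genome).is_file():
        violations.append(f"genome not found: {cfg.genome!r}")
    if not cfg.annotation or not Path(cfg.annotation).is_file():
        violations.append(f"annotation not found: {cfg.annotation!r}")
    for label, path in (("extra_precursors", cfg.extra_precursors), ("fold_structures", cfg.fold_structures)):
        if path and not Path(path).is_file():
            violations.append(f"{label} not found: {path}")
    if cfg.noadapter and cfg.adapter:
        violations.append("NOADAPTER and ADAPTER are mutually exclusive")
    if not cfg.noadapter and not cfg.adapter:
        violations.append("ADAPTER required unless NOADAPTER is set")
    if cfg.adapter and set(cfg.adapter) - set("ACGT"):
        violations.append(f"adapter contains non-ACGT characters: {cfg.adapter}")
    if cfg.min_len > cfg.max_len:
        violations.append("MIN_LEN must be <= MAX_LEN_FILTER")
    if cfg.min_count < 1:
        violations.append("MIN_COUNT must be >= 1")
    if cfg.allowed_overhang < 0:
        violations.append("ALLOWED_OVERHANG must be >= 0")
    if cfg.min_morna_len < 1:
        violations.append("MIN_MORNA_LEN must be >= 1")
    if cfg.morfilter not in ("conservative", "permissive"):
        violations.append("MORFILTER must be 'conservative' or 'permissive'")
    if cfg.max_outside_loci < 0:
        violations.append("MAX_OUTSIDE_LOCI must be >= 0")
    if cfg.threads < 1:
        violations.append("THREADS must be >= 1")
    return violations


@dataclass
class Hairpin:
    """One precursor prepared for assignment: extended sequence + fold."""

    prec: "object"
    ext: hairpin.ExtendedPrecursor
    fold: hairpin.FoldResult
    name: str


@dataclass
class ReferenceSet:
    genome: GenomeRef
    annotation: MirAnnotation
    hairpins: list[Hairpin]
    index: genome_filter.GenomeIndex
    precursor_intervals: list[tuple[str, int, int, str]]


def read_fold_structures(path: str | Path) -> dict[str, str]:
    """2-column TSV (precursor id, dot-bracket) for external-fold mode."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ident, _, structure = line.partition("\t")
            out[ident] = structure
    return out


def prepare_reference(cfg: RunConfig) -> ReferenceSet:
    genome = GenomeRef.from_fasta(cfg.genome)
    annotation = read_mir_gff3(cfg.annotation)
    if cfg.extra_precursors:
        annotation.extend(read_mir_gff3(cfg.extra_precursors))
    fold_map = read_fold_structures(cfg.fold_structures) if cfg.fold_structures else {}
    hairpins: list[Hairpin] = []
    for prec in annotation.precursors:
        ext = hairpin.extend_precursor(prec, annotation.matures_of(prec.id), genome)
        fold_result = hairpin.fold(ext.seq, structure=fold_map.get(prec.id))
        hairpins.append(Hairpin(prec, ext, fold_result, prec.name or prec.id))
    intervals = [(p.chrom, p.start, p.end, p.strand) for p in annotation.precursors]
    index = genome_filter.build_index(genome)
    return ReferenceSet(genome, annotation, hairpins, index, intervals)


@dataclass
class SampleOutput:
    sample: str
    definitions: list[assign_mod.SrnaDefinition]
    records: list[isoform_quant.IsoformRecord]
    unassigned: list[dict]
    stats: dict


def run_sample(sample: str, fastq_path: str, ref: ReferenceSet, cfg: RunConfig) -> SampleOutput:
    pparams = cfg.preprocess_params()
    mparams = cfg.multimap_params()
    aparams = cfg.assign_params()

    tags, ppstats = preprocess.preprocess_sample(
        read_fastq(fastq_path), pparams, noadapter=cfg.noadapter
    )

    kept_tags: list[preprocess.SequenceTag] = []
    n_multimap_discarded = 0
    n_genome_unmapped = 0
    for tag in tags:
        hits, capped = genome_filter.locate_tag(tag, ref.index, ref.precursor_intervals, mparams)
        decision = genome_filter.multimap_filter(hits, capped, mparams)
        if not decision.keep:
            n_multimap_discarded += 1
            continue
        if decision.genome_unmapped:
            n_genome_unmapped += 1
        kept_tags.append(tag)

    # align tags to every extended precursor; 0-mm alignments feed blocks
    aln_by_prec: dict[str, list[assign_mod.PrecursorAlignment]] = {}
    for hp in ref.hairpins:
        alns: list[assign_mod.PrecursorAlignment] = []
        for tag in kept_tags:
            for aln in assign_mod.align_to_precursor(tag, hp.ext):
                if assign_mod.filter_two_mismatch_3prime(aln):
                    alns.append(aln)
        aln_by_prec[hp.ext.id] = alns

    definitions: list[assign_mod.SrnaDefinition] = []
    for hp in ref.hairpins:
        zero_mm = [a for a in aln_by_prec[hp.ext.id] if a.n_mismatches == 0]
        blocks = assign_mod.build_blocks(zero_mm)
        definitions.extend(
            assign_mod.finalize_srnas(hp.ext, hp.fold, blocks, aparams, prec_name=hp.name)
        )
    mors = [d for d in definitions if d.srna_class == "mor"]
    mirs = [d for d in definitions if d.srna_class in ("mir", "new_mir")]
    others = [d for d in definitions if d.srna_class == "loop"]
    kept_mors = assign_mod.mor_sequence_filter(mors, mirs, mode=aparams.morfilter)
    definitions = mirs + kept_mors + others

    defs_by_prec: dict[str, list[assign_mod.SrnaDefinition]] = {}
    for d in definitions:
        defs_by_prec.setdefault(d.precursor_id, []).append(d)

    n_alignments = n_assigned_alignments = 0
    assigned_by_tag: dict[str, list[tuple[assign_mod.PrecursorAlignment, assign_mod.SrnaDefinition]]] = {}
    tags_with_alignment: set[str] = set()
    for hp in ref.hairpins:
        srnas = defs_by_prec.get(hp.ext.id, [])
        per_tag: dict[str, list[assign_mod.PrecursorAlignment]] = {}
        for aln in aln_by_prec[hp.ext.id]:
            per_tag.setdefault(aln.tag.seq, []).append(aln)
        for seq, alns in per_tag.items():
            tags_with_alignment.add(seq)
            alns.sort(key=lambda a: (a.n_mismatches, a.start))
            chosen: Optional[tuple] = None
            for aln in alns:
                n_alignments += 1
                srna = assign_mod.assign_alignment(aln, srnas, aparams)
                if srna is not None:
                    n_assigned_alignments += 1
                    if chosen is None:
                        chosen = (aln, srna)
            if chosen is not None:
                assigned_by_tag.setdefault(seq, []).append(chosen)

    records: list[isoform_quant.IsoformRecord] = []
    unassigned: list[dict] = []
    for tag in kept_tags:
        picks = assigned_by_tag.get(tag.seq, [])
        cross = len({srna.precursor_id for _, srna in picks}) > 1
        if picks:
            for aln, srna in picks:
                records.append(isoform_quant.make_record(aln, srna, cross_mapped=cross))
        elif tag.seq in tags_with_alignment:
            unassigned.append(
                {"sample": sample, "sequence": tag.seq, "count": tag.count, "reason": "no_srna_match"}
            )
        else:
            unassigned.append(
                {
                    "sample": sample,
                    "sequence": tag.seq,
                    "count": tag.count,
                    "reason": "no_precursor_alignment",
                }
            )

    stats = {
        "preprocess": ppstats.as_dict(),
        "tags_kept_multimap": len(kept_tags),
        "tags_discarded_multimap": n_multimap_discarded,
        "tags_genome_unmapped": n_genome_unmapped,
        "alignments_filtered": n_alignments,
        "alignments_assigned": n_assigned_alignments,
        "alignments_unassigned": n_alignments - n_assigned_alignments,
        "srna_definitions": len(definitions),
        "unassigned_tags": len(unassigned),
        "parameters": {
            "MIN_COUNT": cfg.min_count,
            "MIN_LEN": cfg.min_len,
            "MAX_LEN_FILTER": cfg.max_len,
            "MEAN_QUAL_FILTER": cfg.mean_qual,
            "MAX_OUTSIDE_LOCI": cfg.max_outside_loci,
            "ALLOWED_OVERHANG": cfg.allowed_overhang,
            "MIN_MORNA_LEN": cfg.min_morna_len,
            "MORFILTER": cfg.morfilter,
            "NOADAPTER": cfg.noadapter,
            "ADAPTER": cfg.adapter,
        },
    }
    return SampleOutput(sample, definitions, records, unassigned, stats)


_WORKER_REF: dict[int, ReferenceSet] = {}


def _worker(args: tuple[str, str, RunConfig]) -> SampleOutput:
    sample, fastq_path, cfg = args
    key = id(cfg)  # one config per run; reference cached per process
    ref = _WORKER_REF.get(key)
    if ref is None:
        ref = prepare_reference(cfg)
        _WORKER_REF.clear()
        _WORKER_REF[key] = ref
    return run_sample(sample, fastq_path, ref, cfg)


def run_pipeline(cfg: RunConfig, write: bool = True) -> RunResult:
    """Run every sample, aggregate, and (optionally) write the output bundle.

    Samples are independent; with ``threads > 1`` they are processed in
    worker processes, with outputs identical to serial execution.
    """
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    sample_names = sorted(cfg.samples)
    outputs: list[SampleOutput]
    if cfg.threads > 1 and len(sample_names) > 1:
        jobs = [(s, cfg.samples[s], cfg) for s in sample_names]
        with ProcessPoolExecutor(max_workers=cfg.threads) as pool:
            outputs = list(pool.map(_worker, jobs))
    else:
        ref = prepare_reference(cfg)
        outputs = [run_sample(s, cfg.samples[s], ref, cfg) for s in sample_names]
    outputs.sort(key=lambda o: o.sample)

    # catalog: union of per-sample definitions, best-supported per name
    best: dict[str, assign_mod.SrnaDefinition] = {}
    ext_by_id = {}
    annotation = read_mir_gff3(cfg.annotation)
    if cfg.extra_precursors:
        annotation.extend(read_mir_gff3(cfg.extra_precursors))
    genome = GenomeRef.from_fasta(cfg.genome)
    for prec in annotation.precursors:
        ext_by_id[prec.id] = hairpin.extend_precursor(
            prec, annotation.matures_of(prec.id), genome
        )
    for out in outputs:
        for d in out.definitions:
            cur = best.get(d.name)
            if cur is None or d.support_count > cur.support_count:
                best[d.name] = d
    catalog = []
    for d in sorted(best.values(), key=lambda d: (d.precursor_id, d.start)):
        ext = ext_by_id[d.precursor_id]
        gstart, gend = ext.local_to_genomic(d.start, d.end)
        catalog.append(
            CatalogEntry(d.name, d.srna_class, d.precursor_id, ext.chrom, gstart, gend, ext.strand)
        )

    isoforms, counts = isoform_quant.quantify({o.sample: o.records for o in outputs})
    unassigned_rows = [row for o in outputs for row in o.unassigned]
    unassigned = pd.DataFrame(unassigned_rows, columns=["sample", "sequence", "count", "reason"])
    logs = {o.sample: o.stats for o in outputs}
    result = RunResult(
        samples=sample_names,
        catalog=catalog,
        isoforms=isoforms,
        counts=counts,
        unassigned=unassigned,
        logs=logs,
    )
    if write:
        write_outputs(result, cfg.outdir, precursors=annotation.precursors)
    return result
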