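import random

import pytest

from mornaquant.assign import (
    AssignParams,
    PrecursorAlignment,
    SrnaDefinition,
    align_to_precursor,
    assign_alignment,
    build_blocks,
    filter_two_mismatch_3prime,
    finalize_srnas,
    mor_sequence_filter,
)
from mornaquant.hairpin import ExtendedPrecursor, fold
from mornaquant.preprocess import SequenceTag
from mornaquant.simulate import (
    derive_truth,
    make_genome,
    make_hairpin,
    true_extended_structure,
)
from mornaquant.hairpin import extend_precursor


def make_ext(seq, pid="P1"):
    return ExtendedPrecursor(
        id=pid, seq=seq, chrom="c", strand="+", genomic_start=0, flank5=0, flank3=0
    )


def brute_best_stratum(tag_seq, ref, max_mm=2):
    """Oracle: full Hamming scan, then keep the minimum-mismatch stratum."""
    by_mm = {}
    for off in range(len(ref) - len(tag_seq) + 1):
        mm = tuple(i for i in range(len(tag_seq)) if tag_seq[i] != ref[off + i])
        if len(mm) <= max_mm:
            by_mm.setdefault(len(mm), []).append((off, mm))
    for k in range(max_mm + 1):
        if k in by_mm:
            return by_mm[k]
    return []


class TestAlignToPrecursor:
    def test_exact_substring(self):
        ref = "ACGTACGGTTCAGGCATTACGGATCCAGTT"
        ext = make_ext(ref)
        tag = SequenceTag(ref[5:27], 1)
        (aln,) = align_to_precursor(tag, ext)
        assert (aln.start, aln.mismatches) == (5, ())

    def test_last_base_mismatch(self):
        ref = "ACGTACGGTTCAGGCATTACGGATCCAGTT"
        ext = make_ext(ref)
        sub = ref[5:27]
        mutated = sub[:-1] + ("A" if sub[-1] != "A" else "C")
        (aln,) = align_to_precursor(SequenceTag(mutated, 1), ext)
        assert aln.start == 5 and aln.mismatches == (len(sub) - 1,)

    def test_best_stratum_suppresses_worse(self):
        # tag occurs exactly at offset 10 and with 1 mm at offset 40
        core = "TTGGCAGTCGAAGCGGTCAG"
        near = "A" + core[1:]
        ref = "C" * 10 + core + "C" * 10 + near + "C" * 10
        ext = make_ext(ref)
        alns = align_to_precursor(SequenceTag(core, 1), ext)
        assert [(a.start, a.n_mismatches) for a in alns] == [(10, 0)]

    def test_tag_longer_than_reference(self):
        assert align_to_precursor(SequenceTag("A" * 50, 1), make_ext("ACGT" * 10)) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_equivalence_with_brute_force(self, seed):
        rng = random.Random(seed)
        for _ in range(40):
            ref = "".join(rng.choice("ACGT") for _ in range(140))
            ext = make_ext(ref)
            n = rng.randint(16, 28)
            if rng.random() < 0.5:
                pos = rng.randrange(140 - n)
                tag_seq = list(ref[pos : pos + n])
                for p in rng.sample(range(n), k=rng.randint(0, 2)):
                    tag_seq[p] = rng.choice("ACGT")
                tag_seq = "".join(tag_seq)
            else:
                tag_seq = "".join(rng.choice("ACGT") for _ in range(n))
            got = [(a.start, a.mismatches) for a in align_to_precursor(SequenceTag(tag_seq, 1), ext)]
            assert sorted(got) == sorted(brute_best_stratum(tag_seq, ref))


class TestTwoMismatchFilter:
    def aln(self, mm, length=22):
        return PrecursorAlignment(SequenceTag("A" * length, 1), "P", 0, tuple(mm))

    def test_both_terminal_kept(self):
        assert filter_two_mismatch_3prime(self.aln([20, 21]))

    def test_non_terminal_dropped(self):
        assert not filter_two_mismatch_3prime(self.aln([0, 21]))

    def test_single_mismatch_always_kept(self):
        assert filter_two_mismatch_3prime(self.aln([7]))

    def test_zero_mismatch_kept(self):
        assert filter_two_mismatch_3prime(self.aln([]))


def _aln(seq, count, start, pid="P1"):
    return PrecursorAlignment(SequenceTag(seq, count), pid, start)


class TestBuildBlocks:
    def test_two_pileups_forty_nt_apart(self):
        alns = [_aln("A" * 22, 50, 10), _aln("C" * 22, 30, 50)]
        blocks = build_blocks(alns)
        assert [(b.start, b.end) for b in blocks] == [(10, 32), (50, 72)]

    def test_single_tag(self):
        (b,) = build_blocks([_aln("A" * 20, 5, 33)])
        assert (b.start, b.end) == (33, 53) and b.total_count == 5

    def test_staggered_ends_join_dominant(self):
        dominant = _aln("G" * 22, 100, 30)
        shifted = [_aln("T" * 22, c, 30 + d) for c, d in ((10, 1), (5, 2), (3, 3))]
        blocks = build_blocks([dominant] + shifted)
        assert len(blocks) == 1
        assert blocks[0].representative is dominant
        assert blocks[0].total_count == 118

    def test_rejects_mismatched_alignments(self):
        bad = PrecursorAlignment(SequenceTag("A" * 20, 1), "P1", 0, (3,))
        with pytest.raises(ValueError):
            build_blocks([bad])

    @pytest.mark.parametrize("seed", range(5))
    def test_blocks_pairwise_non_overlapping(self, seed):
        rng = random.Random(seed)
        alns = [
            _aln("ACGT" * 5 + "AC", rng.randint(1, 100), rng.randrange(100))
            for _ in range(rng.randint(1, 40))
        ]
        blocks = build_blocks(alns)
        ivs = sorted((b.start, b.end) for b in blocks)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 <= s2
        assert sum(b.total_count for b in blocks) == sum(a.tag.count for a in alns)


def _one_design_setup(seed=21, mature_arm="5p"):
    design = make_hairpin(seed, mature_arm=mature_arm, loop_len=22, name="sim-mir-9")
    genome, ann, _ = make_genome([design], seed=seed, genome_len=6000, strands=["+"])
    prec = ann.precursors[0]
    ext = extend_precursor(prec, ann.matures_of(prec.id), genome)
    truth = derive_truth(design, ext, {"mir": 100, "new_mir": 60, "mor5p": 40, "mor3p": 30, "loop": 20})
    fr = fold(ext.seq, structure=true_extended_structure(design, ext))
    return ext, fr, truth


class TestFinalizeSrnas:
    def test_definitions_from_planted_blocks(self):
        ext, fr, truth = _one_design_setup()
        alns = []
        for t in truth:
            (a,) = align_to_precursor(SequenceTag(t.seq, t.count), ext)
            assert a.start == t.start
            alns.append(a)
        defs = finalize_srnas(ext, fr, build_blocks(alns), AssignParams(), prec_name="sim-mir-9")
        got = {(d.srna_class, d.arm): (d.start, d.end) for d in defs}
        expected = {(t.srna_class, t.arm): (t.start, t.end) for t in truth}
        assert got == expected
        names = {d.name for d in defs}
        assert names == {t.name for t in truth}

    def test_at_most_four_plus_loop(self):
        ext, fr, truth = _one_design_setup()
        alns = [align_to_precursor(SequenceTag(t.seq, t.count), ext)[0] for t in truth]
        defs = finalize_srnas(ext, fr, build_blocks(alns), AssignParams(), prec_name="x")
        assert sum(1 for d in defs if d.srna_class != "loop") <= 4
        assert sum(1 for d in defs if d.srna_class == "loop") <= 1

    def test_short_flank_block_not_called_mor(self):
        ext, fr, truth = _one_design_setup()
        mor = next(t for t in truth if t.name.endswith("moR-9-5p") or t.arm == "5p" and t.srna_class == "mor")
        short = SequenceTag(mor.seq[:14], 50)  # below min_morna_len
        alns = align_to_precursor(short, ext)
        zero = [a for a in alns if a.n_mismatches == 0]
        defs = finalize_srnas(ext, fr, build_blocks(zero), AssignParams(), prec_name="x")
        assert all(d.srna_class != "mor" for d in defs)


class TestMorSequenceFilter:
    def mor(self, seq):
        return SrnaDefinition("P1", "mor", "5p", 0, len(seq), "moR-a-5p", seq)

    def mir(self, seq, pid="P2"):
        return SrnaDefinition(pid, "mir", "5p", 0, len(seq), "miR-b-5p", seq)

    def test_conservative_removes_shared_sequence(self):
        shared = "ACGGTTCAGGCATTACGGAT"
        assert mor_sequence_filter([self.mor(shared)], [self.mir(shared)]) == []

    def test_permissive_keeps(self):
        shared = "ACGGTTCAGGCATTACGGAT"
        kept = mor_sequence_filter([self.mor(shared)], [self.mir(shared)], mode="permissive")
        assert len(kept) == 1

    def test_substring_containment_removed(self):
        mor = self.mor("TTCAGGCATTACGGAT")
        mir = self.mir("ACG" + mor.seq + "CA")
        assert mor_sequence_filter([mor], [mir]) == []

    def test_partial_terminal_overlap_kept(self):
        mor = self.mor("AAAAATTTTTGGGGGCCCCC")
        mir = self.mir("GGGCCCCCTTTTTAAAAACG")  # shares only terminal bases, no containment
        assert mor_sequence_filter([mor], [mir]) == [mor]


class TestAssignAlignment:
    def setup_method(self):
        self.mor = SrnaDefinition("P1", "mor", "5p", 10, 30, "moR-x-5p", "A" * 20)
        self.mir = SrnaDefinition("P1", "mir", "5p", 10, 30, "miR-x-5p", "A" * 20)

    def aln(self, start, end, pid="P1"):
        return PrecursorAlignment(SequenceTag("A" * (end - start), 1), pid, start)

    def test_exact_mor_read(self):
        assert assign_alignment(self.aln(10, 30), [self.mor], AssignParams()) is self.mor

    def test_overhang_boundary_4(self):
        aln = self.aln(6, 30)  # extends 4 nt past the 5' end
        assert assign_alignment(aln, [self.mor], AssignParams(allowed_overhang=3)) is None
        got = assign_alignment(aln, [self.mor], AssignParams(allowed_overhang=4))
        assert got is self.mor

    def test_class_precedence_on_tie(self):
        aln = self.aln(10, 30)
        got = assign_alignment(aln, [self.mor, self.mir], AssignParams())
        assert got is self.mir

    def test_other_precursor_not_considered(self):
        assert assign_alignment(self.aln(10, 30, pid="P2"), [self.mor], AssignParams()) is None


def test_assignment_partition_on_pipeline(run_result):
    for sample, stats in run_result.logs.items():
        assert (
            stats["alignments_assigned"] + stats["alignments_unassigned"]
            == stats["alignments_filtered"]
        )


def test_catalog_per_precursor_limits(run_result):
    per_prec = {}
    for entry in run_result.catalog:
        per_prec.setdefault(entry.precursor_id, []).append(entry.srna_class)
    for classes in per_prec.values():
        assert sum(1 for c in classes if c != "loop") <= 4
        assert classes.count("loop") <= 1


def test_overhang_monotonicity(bundle, sim_paths, tmp_path):
    from conftest import make_run_config
    from mornaquant.pipeline import run_pipeline

    cfg3 = make_run_config(bundle, sim_paths, tmp_path / "o3", allowed_overhang=3)
    cfg4 = make_run_config(bundle, sim_paths, tmp_path / "o4", allowed_overhang=4)
    r3 = run_pipeline(cfg3)
    r4 = run_pipeline(cfg4)
    a3 = sum(s["alignments_assigned"] for s in r3.logs.values())
    a4 = sum(s["alignments_assigned"] for s in r4.logs.values())
    assert a4 >= a3


def test_params_invariants():
    with pytest.raises(ValueError):
        AssignParams(allowed_overhang=-1)
    with pytest.raises(ValueError):
        AssignParams(morfilter="bogus")
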