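import random
from functools import lru_cache

import pytest

from mornaquant.formats_io import GenomeRef, Mature, Precursor, revcomp
from mornaquant.hairpin import (
    FoldResult,
    MorGeometry,
    arm_of,
    can_pair,
    candidate_mor_geometry,
    extend_precursor,
    fold,
    parse_dot_bracket,
    project_star,
)
from mornaquant.simulate import make_hairpin


# ---------------------------------------------------------------- oracles


def max_pairs_oracle(seq: str) -> int:
    """Max base pairs via a top-down search over all nested structures,
    independent of the production folder (pairs the RIGHT end of each
    interval; memoized interval recursion)."""
    seq = seq.upper().replace("U", "T")

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if j - i < 4:
            return 0
        best = rec(i, j - 1)  # j unpaired
        for k in range(i, j - 3):
            if can_pair(seq[k], seq[j]):
                left = rec(i, k - 1) if k - 1 >= i else 0
                best = max(best, left + 1 + rec(k + 1, j - 1))
        return best

    return rec(0, len(seq) - 1)


def enumerate_all_structures(seq: str):
    """Literal enumeration of every nested pair set (tiny inputs only)."""
    seq = seq.upper().replace("U", "T")

    def rec(i, j):
        if i > j:
            yield frozenset()
            return
        yield from rec(i + 1, j)
        for k in range(i + 4, j + 1):
            if can_pair(seq[i], seq[k]):
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield left | right | {(i, k)}

    yield from rec(0, len(seq) - 1)


def test_oracle_agrees_with_literal_enumeration():
    rng = random.Random(1)
    for _ in range(20):
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 12)))
        literal = max((len(s) for s in enumerate_all_structures(seq)), default=0)
        assert max_pairs_oracle(seq) == literal


# ---------------------------------------------------------------- extend


def _genome(seq):
    return GenomeRef({"chr1": seq})


def test_extend_mid_chromosome():
    rng = random.Random(0)
    chrom = "".join(rng.choice("ACGT") for _ in range(400))
    g = _genome(chrom)
    prec = Precursor("P1", "chr1", 100, 180, "+")
    ext = extend_precursor(prec, [], g)
    assert len(ext.seq) == 140
    assert (ext.flank5, ext.flank3) == (30, 30)
    assert ext.seq == chrom[70:210]


def test_extend_truncated_at_contig_start():
    g = _genome("ACGT" * 50)
    prec = Precursor("P1", "chr1", 10, 90, "+")
    ext = extend_precursor(prec, [], g)
    assert ext.flank5 == 10 and ext.flank3 == 30


def test_extend_minus_strand_is_revcomp():
    rng = random.Random(1)
    chrom = "".join(rng.choice("ACGT") for _ in range(400))
    g = _genome(chrom)
    prec = Precursor("P1", "chr1", 100, 180, "-")
    ext = extend_precursor(prec, [], g)
    assert ext.seq == revcomp(chrom[70:210])
    # local coordinate 0 is the transcript 5' end = genomic end side
    assert ext.local_to_genomic(0, 1) == (209, 210)


def test_extend_missing_chrom_errors():
    with pytest.raises(KeyError):
        extend_precursor(Precursor("P1", "chrX", 10, 90, "+"), [], _genome("ACGT" * 100))


@pytest.mark.parametrize("strand", ["+", "-"])
def test_local_genomic_round_trip(strand):
    rng = random.Random(2)
    chrom = "".join(rng.choice("ACGT") for _ in range(500))
    g = _genome(chrom)
    prec = Precursor("P1", "chr1", 150, 250, strand)
    mat = Mature("M1", "P1", "chr1", 170, 192, strand)
    ext = extend_precursor(prec, [mat], g)
    local = ext.matures["M1"]
    assert ext.local_to_genomic(*local) == (170, 192)
    assert ext.genomic_to_local(170, 192) == local
    # the local slice equals the transcribed mature sequence
    assert ext.seq[local[0] : local[1]] == g.fetch("chr1", 170, 192, strand)


def test_round_trip_on_simulated_annotation(bundle):
    for prec in bundle.annotation.precursors:
        mats = bundle.annotation.matures_of(prec.id)
        ext = extend_precursor(prec, mats, bundle.genome)
        for m in mats:
            assert ext.local_to_genomic(*ext.matures[m.name]) == (m.start, m.end)


# ---------------------------------------------------------------- fold


def test_fold_perfect_mini_hairpin():
    r = fold("GGGGAAAACCCC")
    assert r.structure == "((((....))))"
    assert r.n_pairs == 4


def test_fold_unpairable_sequence():
    assert fold("AAAAAAAAAA").structure == "." * 10


def test_fold_too_short():
    with pytest.raises(ValueError):
        fold("ACGTACG")


def test_external_mode_min_loop_violation_rejected():
    with pytest.raises(ValueError):
        fold("GGGCCC", structure="((..))")


def test_external_mode_unbalanced_rejected():
    with pytest.raises(ValueError):
        fold("GGGGAAAACCCC", structure="(((....)))).")


def test_external_mode_valid_structure_accepted():
    r = fold("GGGGAAAACCCC", structure="((((....))))")
    assert r.pairs[0] == 11


@pytest.mark.parametrize("seed", range(8))
def test_fold_matches_enumeration_oracle(seed):
    rng = random.Random(seed)
    for _ in range(6):
        n = rng.randint(10, 18)
        seq = "".join(rng.choice("ACGT") for _ in range(n))
        assert fold(seq).n_pairs == max_pairs_oracle(seq)


def test_fold_invariants_random_sequences():
    rng = random.Random(9)
    for _ in range(10):
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 60)))
        r = fold(seq)
        for i, j in enumerate(r.pairs):
            if j != -1:
                assert r.pairs[j] == i
                assert abs(i - j) >= 4
                assert can_pair(*sorted((seq[i], seq[j]))) or can_pair(seq[i], seq[j])
        assert r.structure.count("(") == r.structure.count(")")


def test_fold_recovers_designed_stem():
    d = make_hairpin(3, stem_len=25, loop_len=8, mir_len=22)
    r = fold(d.seq)
    K = 2 * d.stem_len + d.loop_len - 1
    assert all(r.pairs[i] == K - i for i in range(d.stem_len))


# ---------------------------------------------------------------- star


def _perfect_fold(stem, loop):
    structure = "(" * stem + "." * loop + ")" * stem
    return FoldResult(structure=structure, pairs=parse_dot_bracket(structure))


def test_star_perfect_duplex_5p_mature():
    stem, loop = 25, 8
    fr = _perfect_fold(stem, loop)
    K = 2 * stem + loop - 1
    mature = (3, 25)  # on 5' arm
    star = project_star(mature, fr)
    assert star == (K - 25 + 3, K - 3 + 3)
    assert star[1] - star[0] == 22  # length preserved


def test_star_perfect_duplex_property_random_placements():
    stem, loop = 30, 10
    fr = _perfect_fold(stem, loop)
    n = 2 * stem + loop
    K = n - 1
    rng = random.Random(4)
    for _ in range(50):
        arm = rng.choice(["5p", "3p"])
        length = rng.randint(18, 24)
        if arm == "5p":
            a = rng.randint(0, stem - length)
        else:
            a = rng.randint(stem + loop, n - length)
        star = project_star((a, a + length), fr)
        expected = (max(0, K - (a + length) + 3), min(n, K - a + 3))
        assert star == expected


def test_star_mostly_unpaired_mature_returns_none():
    # 5 paired of 10 mature positions -> 50% < 60%
    fr = _perfect_fold(5, 6)
    assert project_star((0, 10), fr) is None


def test_star_rejected_when_overlapping_annotated_mature():
    fr = _perfect_fold(25, 8)
    mature = (3, 25)
    other = (36, 58)  # annotated mature sitting on the 3' arm
    assert project_star(mature, fr, annotated=[other]) is None
    far = (0, 2)
    assert project_star(mature, fr, annotated=[mature, far]) is not None


def test_star_spans_bulge_in_star_arm():
    # 10-nt mature, 4-nt loop, star arm interrupted by a 3-nt bulge
    structure = "(" * 10 + "...." + ")" * 5 + "..." + ")" * 5
    fr = FoldResult(structure=structure, pairs=parse_dot_bracket(structure))
    # independent pairing-partner scan from the dot-bracket
    stack, partner = [], {}
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            partner[stack.pop()] = i
    partners = [partner[i] for i in range(0, 10)]
    mn, mx = min(partners), max(partners)
    expected = (mn + 2, min(len(structure), mx + 3))
    star = project_star((0, 10), fr)
    assert star == expected
    assert star[0] < 19 < star[1]  # bulge positions inside the star interval


# ---------------------------------------------------------------- geometry


def _fake_ext(n=140):
    return type("E", (), {"seq": "A" * n})()


def test_geometry_both_arms():
    ext = _fake_ext(140)
    geo = candidate_mor_geometry(ext, (30, 52), (80, 102))
    assert geo.mor5p_window == (0, 33)
    assert geo.mor3p_window == (99, 140)
    assert geo.loop == (52, 80)


def test_geometry_only_5p_arm():
    geo = candidate_mor_geometry(_fake_ext(), (30, 52), None)
    assert geo.mor5p_window == (0, 33)
    assert geo.mor3p_window is None and geo.loop is None


def test_geometry_example_window_arithmetic():
    geo = candidate_mor_geometry(_fake_ext(), (30, 52), (80, 102), overlap_slack=3)
    assert geo.mor5p_window == (0, 33)


def test_arm_of_uses_loop_hinge():
    fr = _perfect_fold(25, 8)
    assert arm_of((0, 22), fr) == "5p"
    assert arm_of((36, 58), fr) == "3p"
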