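"""Folding and stem-loop machinery against independent oracles."""

import itertools

import numpy as np
import pytest

from mobscan.errors import AlphabetError, GeometryError
from mobscan.rna_structure import (can_pair, find_stem_loops, nussinov_fold,
                                   pair_fraction)
from mobscan.seq_core import revcomp


def brute_force_max_pairs(seq, min_loop=3, allow_gu=True):
    """Exhaustive enumeration of all non-crossing pairings (n <= ~14);
    independent of the DP recurrence: splits on the leftmost position."""
    n = len(seq)

    def enumerate_best(positions):
        if len(positions) < 2:
            return 0
        i = positions[0]
        rest = positions[1:]
        score = enumerate_best(rest)
        for idx, j in enumerate(rest):
            if j - i > min_loop and can_pair(seq[i], seq[j], allow_gu):
                inside = [p for p in rest[:idx]]
                outside = [p for p in rest[idx + 1:]]
                score = max(score,
                            1 + enumerate_best(inside) + enumerate_best(outside))
        return score

    return enumerate_best(list(range(n)))


@pytest.mark.parametrize("seq,expected", [
    ("GGGGAAAACCCC", 4),   # frozen from brute-force enumeration
    ("AAAA", 0),           # no complementary pairs
    ("", 0),
])
def test_nussinov_examples(seq, expected):
    res = nussinov_fold(seq)
    assert res.max_pairs == expected
    if seq:
        assert res.max_pairs == brute_force_max_pairs(seq)


def test_nussinov_dot_bracket_consistency_and_bound():
    rng = np.random.default_rng(2)
    for _ in range(30):
        seq = "".join(rng.choice(list("ACGU"), size=int(rng.integers(1, 25))))
        res = nussinov_fold(seq)
        assert res.dot_bracket.count("(") == res.max_pairs == len(res.pairs)
        assert res.dot_bracket.count(")") == res.max_pairs
        assert res.max_pairs <= len(seq) // 2
        for i, j in res.pairs:
            assert j - i > 3
            assert can_pair(res.sequence[i], res.sequence[j])


def test_nussinov_matches_bruteforce_small():
    rng = np.random.default_rng(4)
    for _ in range(60):
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(4, 13))))
        assert nussinov_fold(seq).max_pairs == brute_force_max_pairs(seq)


def test_nussinov_rejects_bad_alphabet():
    with pytest.raises(AlphabetError):
        nussinov_fold("ACGX")


def _planted_hairpin(rng, stem=8, loop=5, flank=15):
    arm = "".join(rng.choice(list("ACGT"), size=stem))
    hp = arm + "".join(rng.choice(list("ACGT"), size=loop)) + revcomp(arm)
    left = "A" * 2 + "".join(rng.choice(list("ACGT"), size=flank))
    right = "".join(rng.choice(list("ACGT"), size=flank))
    return left + "AA" + hp + "AA" + right, len(left) + 2, len(left) + 2 + len(hp)


def test_stem_loop_planted_recovered_exactly():
    rng = np.random.default_rng(6)
    seq, start, end = _planted_hairpin(rng)
    hits = find_stem_loops(seq, min_stem=5)
    assert hits, "planted hairpin not found"
    top = hits[0]
    assert (top.start, top.end) == (start, end)
    assert top.stem_pairs == 8 and top.loop_len == 5 and top.bulges == 0
    assert top.score == 8.0


def test_stem_loop_mirrored_on_reverse_strand():
    rng = np.random.default_rng(8)
    seq, start, end = _planted_hairpin(rng)
    mirrored = find_stem_loops(revcomp(seq), min_stem=5)[0]
    assert (mirrored.start, mirrored.end) == (len(seq) - end, len(seq) - start)


def test_stem_loop_beats_dinucleotide_shuffle_null():
    # empirical null: the planted perfect stem outranks the best stem of a
    # dinucleotide-shuffled control (perfect-WC scan, so composition alone
    # cannot reassemble an equivalent stem) in >= 95/100 shuffles
    rng = np.random.default_rng(10)
    scan = dict(min_stem=4, max_bulge=0, allow_gu=False)
    seq, start, end = _planted_hairpin(rng, stem=8, loop=5, flank=10)
    planted_score = find_stem_loops(seq, **scan)[0].score
    assert planted_score == 8.0
    wins = 0
    for _ in range(100):
        dinucs = [seq[i:i + 2] for i in range(0, len(seq) - 1, 2)]
        rng.shuffle(dinucs)
        shuffled = "".join(dinucs)
        hits = find_stem_loops(shuffled, **scan)
        top = hits[0].score if hits else 0.0
        wins += top < planted_score
    assert wins >= 95


def test_pair_fraction_examples():
    box = "ACCTAGG"
    assert pair_fraction(box, revcomp(box)) == 1.0
    mism = revcomp(box)
    mism = mism[:3] + ("A" if mism[3] != "A" else "C") + mism[4:]
    assert pair_fraction(box, mism) == pytest.approx(6 / 7)
    with pytest.raises(GeometryError):
        pair_fraction("ACGTACG", "ACGT")


def test_pair_fraction_random_expectation_matches_enumeration():
    # exact per-position probability under uniform composition, WC only
    p_exact = sum((b1, b2) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
                  for b1, b2 in itertools.product("ACGT", repeat=2)) / 16
    assert p_exact == 0.25
    rng = np.random.default_rng(12)
    draws = [pair_fraction("".join(rng.choice(list("ACGT"), size=7)),
                           "".join(rng.choice(list("ACGT"), size=7)))
             for _ in range(1000)]
    se = np.sqrt(p_exact * (1 - p_exact) / (7 * 1000))
    assert abs(np.mean(draws) - p_exact) < 4 * se


def test_pair_fraction_gu_mode_expectation():
    p_exact = sum((b1, b2) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                               ("G", "T"), ("T", "G")}
                  for b1, b2 in itertools.product("ACGT", repeat=2)) / 16
    assert p_exact == 0.375
    rng = np.random.default_rng(13)
    draws = [pair_fraction("".join(rng.choice(list("ACGT"), size=7)),
                           "".join(rng.choice(list("ACGT"), size=7)),
                           allow_gu=True)
             for _ in range(1000)]
    se = np.sqrt(p_exact * (1 - p_exact) / (7 * 1000))
    assert abs(np.mean(draws) - p_exact) < 4 * se
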