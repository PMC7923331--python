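"""attC detection, clustering, cassette delineation and locus classification."""

import numpy as np
import pytest

from mobscan.attc import (AttCConfig, AttCSite, IntegronLocus, classify_locus,
                          cluster_attc, delineate_cassettes, scan_attc)
from mobscan.errors import ConfigurationError, InputError
from mobscan.seq_core import GenomicSequence, Interval, ORFRecord, find_orfs, revcomp
from mobscan.synthetic import _Builder, _place_attc_site, _rand_dna, back_translate


def _landscape_with_site(seed=0, pad=300):
    rng = np.random.default_rng(seed)
    b = _Builder()
    b.add(_rand_dna(rng, pad))
    feat = _place_attc_site(b, rng)
    b.add(_rand_dna(rng, pad))
    return b.seq(), feat


def test_scan_attc_recovers_planted_site_with_exact_boxes():
    seq, feat = _landscape_with_site()
    sites = scan_attc(seq)
    assert len(sites) == 1
    s = sites[0]
    assert (s.interval.start, s.interval.end) == feat.interval
    assert s.strand == "+" and s.bs_strand == "-"
    assert (s.box_r2.start, s.box_r2.end) == feat.anchors["r2"]
    assert (s.box_l2.start, s.box_l2.end) == feat.anchors["l2"]
    assert (s.box_l1.start, s.box_l1.end) == feat.anchors["l1"]
    assert (s.box_r1.start, s.box_r1.end) == feat.anchors["r1"]
    assert s.r_pairing == pytest.approx(6 / 7)
    assert s.l_pairing == 1.0
    # box order invariant along the site
    assert s.box_r2.end <= s.box_l2.start < s.box_l1.start < s.box_r1.start


def test_scan_attc_reverse_complement_mirrors_site():
    seq, feat = _landscape_with_site(seed=1)
    L = len(seq)
    sites = scan_attc(revcomp(seq))
    assert len(sites) == 1
    s = sites[0]
    assert s.strand == "-" and s.bs_strand == "+"
    assert (s.interval.start, s.interval.end) == (L - feat.interval[1],
                                                  L - feat.interval[0])


def test_scan_attc_l_box_mismatch_budget():
    seq, feat = _landscape_with_site(seed=2)
    l2_start, _ = feat.anchors["l2"]
    mutated = list(seq)
    for off in (1, 4):   # two substitutions inside L''
        pos = l2_start + off
        mutated[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos]]
    mutated = "".join(mutated)
    tolerant = AttCConfig(min_l_pairing=0.8)     # allows 2 mispaired of 10
    strict = AttCConfig(min_l_pairing=0.95)      # allows at most 0 mispaired
    assert len(scan_attc(mutated, tolerant)) == 1
    assert scan_attc(mutated, strict) == []


def _site_at(start, seq_id="s"):
    iv = lambda a, b: Interval(seq_id, a, b)
    return AttCSite(interval=iv(start, start + 52), strand="+",
                    box_r2=iv(start, start + 7), box_l2=iv(start + 12, start + 22),
                    box_l1=iv(start + 30, start + 40),
                    box_r1=iv(start + 45, start + 52),
                    r_pairing=6 / 7, l_pairing=1.0, fold_score=20, score=16.0)


def test_cluster_attc_distance_threshold_boundaries():
    # inter-site gap 7,999 bp -> one locus; 8,001 bp -> both sites singletons
    near = [_site_at(0), _site_at(52 + 7999)]
    far = [_site_at(0), _site_at(52 + 8001)]
    assert len(cluster_attc(near)) == 1
    assert cluster_attc(far) == []
    chain = [_site_at(0), _site_at(7000), _site_at(14000)]
    loci = cluster_attc(chain)
    assert len(loci) == 1 and len(loci[0].sites) == 3


def test_cluster_attc_rejects_mixed_sequences():
    with pytest.raises(InputError):
        cluster_attc([_site_at(0, "a"), _site_at(100, "b")])


def _brute_force_clusters(starts, threshold):
    """O(n^2) transitive closure over the 'within threshold' relation."""
    n = len(starts)
    ivs = sorted((s, s + 52) for s in starts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            gap = max(ivs[j][0] - ivs[i][1], ivs[i][0] - ivs[j][1])
            if gap <= threshold:
                ri, rj = find(i), find(j)
                parent[max(ri, rj)] = min(ri, rj)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(ivs[i])
    return sorted([sorted(g) for g in groups.values() if len(g) >= 2])


def test_cluster_attc_matches_transitive_closure_oracle():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n = int(rng.integers(2, 12))
        starts = sorted(int(x) for x in
                        rng.choice(np.arange(0, 60000, 100), size=n,
                                   replace=False))
        sites = [_site_at(s) for s in starts]
        got = sorted(
            [sorted((x.interval.start, x.interval.end) for x in locus.sites)
             for locus in cluster_attc(sites, threshold_bp=8000)])
        assert got == _brute_force_clusters(starts, 8000)


def _orf_at(start, end, seq_id="s", strand="+"):
    return ORFRecord(interval=Interval(seq_id, start, end, strand), frame=0,
                     has_start=True, has_stop=True,
                     protein="M" * ((end - start) // 3 - 1))


def test_delineate_cassettes_counts_and_orf_assignment():
    locus = IntegronLocus(seq_id="s",
                          sites=[_site_at(3000), _site_at(5000), _site_at(8000)])
    orfs = [_orf_at(3300, 3600)] + [_orf_at(5100 + 300 * i, 5300 + 300 * i)
                                    for i in range(6)]
    delineate_cassettes(locus, orfs, leader_bp=2000)
    assert len(locus.cassettes) == 3          # leader + 2 internal
    assert locus.cassettes[0].interval.start == 1000
    assert len(locus.cassettes[1].orfs) == 1
    assert len(locus.cassettes[2].orfs) == 6  # one cassette may hold 6 ORFs


def test_delineate_cassettes_flags_boundary_spanning_orf():
    locus = IntegronLocus(seq_id="s", sites=[_site_at(3000), _site_at(5000)])
    # midpoint (4975) falls inside the cassette, but the ORF end exceeds it
    straddler = _orf_at(4800, 5150)
    delineate_cassettes(locus, [straddler], leader_bp=500)
    cass = locus.cassettes[1]
    assert len(cass.orfs) == 1
    assert cass.boundary_spanning == [0]


def test_classify_locus_complete_vs_calin(panels):
    rng = np.random.default_rng(23)
    inti = panels.inti[0]
    gene = "TAAATG" + back_translate(inti.protein) + "TAA"

    def build(inti_offset=None, length=70000):
        sites = [_site_at(30000, "g"), _site_at(31000, "g")]
        seq = _rand_dna(rng, length)
        if inti_offset is not None:
            seq = seq[:inti_offset] + gene + seq[inti_offset + len(gene):]
        locus = IntegronLocus(seq_id="g", sites=sites)
        orfs = find_orfs(seq, min_len=150, seq_id="g")
        return seq, locus, orfs

    seq, locus, orfs = build(inti_offset=28000)
    classify_locus(seq, locus, panels.inti, orfs)
    assert locus.classification == "complete_integron"
    assert locus.intI_hit is not None

    seq, locus, orfs = build(inti_offset=None)
    classify_locus(seq, locus, panels.inti, orfs)
    assert locus.classification == "CALIN" and locus.intI_hit is None

    # intI ~19 kb upstream of the array with a 10 kb window -> still a CALIN
    seq, locus, orfs = build(inti_offset=10000)
    classify_locus(seq, locus, panels.inti, orfs, window_bp=10000)
    assert locus.classification == "CALIN"

    with pytest.raises(ConfigurationError):
        classify_locus(seq, locus, [], orfs)


def test_scan_attc_specificity_on_random_background():
    """Empirical specificity: no false attC calls on pure-random sequence."""
    rng = np.random.default_rng(99)
    false_positives = 0
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), size=100_000))
        false_positives += len(scan_attc(seq))
    assert false_positives <= 1
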