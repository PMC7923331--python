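"""IEP detection, boundary/structure inference, target-site analysis,
classification and integrity calls."""

import numpy as np
import pytest

from mobscan.errors import ConfigurationError
from mobscan.introns import (IntronConfig, IntronModel, Roi, call_integrity,
                             check_iic_attc_context, classify_intron,
                             detect_iep, find_div_basal_stem,
                             find_five_prime_end, find_three_prime_end,
                             map_ebs_ibs)
from mobscan.panels import PanelEntry, synthetic_iep_panel
from mobscan.seq_core import Interval, ORFRecord, find_orfs
from mobscan.synthetic import (_Builder, _intron_construct, _rand_dna, _rc,
                               back_translate)


def _orf_record(protein, start=0, strand="+", seq_id="s"):
    end = start + 3 * len(protein) + 6
    return ORFRecord(interval=Interval(seq_id, start, end, strand), frame=0,
                     has_start=True, has_stop=True, protein=protein)


# ---------------------------------------------------------------------------
# detect_iep
# ---------------------------------------------------------------------------

def test_detect_iep_self_alignment_full_domains(panels):
    ref = panels.iep[0]
    hits = detect_iep([_orf_record(ref.protein)], panels.iep)
    assert len(hits) == 1
    hit = hits[0]
    assert hit.best_ref.id == ref.id
    assert hit.identity == pytest.approx(100.0)
    assert hit.similarity >= hit.identity
    assert all(hit.domain_coverage[d] == "present"
               for d in ("RT0", "RT5", "RT7", "X"))
    assert hit.yadd == "present" and hit.frame_disruptions == 0


def test_detect_iep_n_terminal_truncation_loses_rt0_rt4(panels):
    ref = panels.iep[0]
    partial = ref.protein[200:]        # N-terminus through RT4 removed
    hit = detect_iep([_orf_record(partial)], panels.iep)[0]
    for d in ("RT0", "RT1", "RT2", "RT3", "RT4"):
        assert hit.domain_coverage[d] in ("absent", "partial")
    for d in ("RT5", "RT6", "RT7", "X"):
        assert hit.domain_coverage[d] == "present"
    assert hit.yadd == "present"


def test_detect_iep_engineered_yadd_knockout(panels):
    ref = panels.iep[0]
    prot = ref.protein.replace("YADD", "YAAA")
    hit = detect_iep([_orf_record(prot)], panels.iep)[0]
    assert hit.yadd == "absent"


def test_detect_iep_merges_disrupted_frame(panels):
    ref = panels.iep[0]
    half = len(ref.protein) // 2
    part1 = _orf_record(ref.protein[:half], start=0)
    part2 = _orf_record(ref.protein[half:], start=part1.interval.end + 30)
    hits = detect_iep([part1, part2], panels.iep)
    assert len(hits) == 1
    assert hits[0].frame_disruptions == 1
    assert all(hits[0].domain_coverage[d] == "present"
               for d in ("RT0", "RT5", "X"))


def test_detect_iep_requires_domain_annotations(panels):
    bare = [PanelEntry(id="x", role="iep", label="E", protein="MKL" * 100)]
    with pytest.raises(ConfigurationError):
        detect_iep([], bare)
    with pytest.raises(ConfigurationError):
        detect_iep([], [])


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_classify_intron_reference_recovers_own_class(panels):
    for ref in panels.iep[::4]:
        hit = detect_iep([_orf_record(ref.protein)], panels.iep)[0]
        label, scores = classify_intron(hit, panels.iep)
        assert label == ref.label


def test_classify_intron_leave_one_out_within_class():
    panel = synthetic_iep_panel()
    for held_out in panel[::5]:
        rest = [e for e in panel if e.id != held_out.id]
        hit = detect_iep([_orf_record(held_out.protein)], rest)[0]
        label, scores = classify_intron(hit, rest)
        assert label == held_out.label


def test_classify_intron_chimera_is_ambiguous(panels):
    # mosaic of 10-residue blocks alternating between two classes sits at
    # equal distance from both: the margin rule must refuse to call it
    a = next(e for e in panels.iep if e.label == "CL1")
    b = next(e for e in panels.iep if e.label == "E")
    chimera = "".join((a if (i // 10) % 2 == 0 else b).protein[i]
                      for i in range(len(a.protein)))
    hit_refs = detect_iep([_orf_record(chimera)], panels.iep)
    label, scores = classify_intron(hit_refs[0], panels.iep, margin=5.0)
    assert label == "ambiguous"
    assert {"CL1", "E"} <= set(scores)


# ---------------------------------------------------------------------------
# boundary and structure inference on a standalone planted intron
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted(panels):
    rng = np.random.default_rng(41)
    iep = next(e for e in panels.iep if e.label == "CL1")
    ibs2, ibs1, ibs3 = "CTGAAC", "TCATGG", "C"
    construct, anchors, _ = _intron_construct(rng, iep, triad="AGC",
                                              ibs1=ibs1, ibs3=ibs3, ibs2=ibs2)
    b = _Builder()
    b.add(_rand_dna(rng, 700))
    b.add(ibs2 + ibs1)
    p = b.add(construct)
    b.add(ibs3)
    b.add(_rand_dna(rng, 500))
    seq = b.seq()
    orf_iv = Interval("s", anchors["orf"][0] + p, anchors["orf"][1] + p, "+")
    roi = Roi(seq, orf_iv, IntronConfig(), seq_id="s")
    return dict(seq=seq, offset=p, anchors=anchors, roi=roi, iep=iep)


def test_three_prime_end_found_at_planted_position(planted):
    roi, p, anchors = planted["roi"], planted["offset"], planted["anchors"]
    res = find_three_prime_end(roi, intron_class="IIB")
    assert res is not None
    assert roi.pos_to_top(res.three_o) == anchors["three"] + p
    assert res.triad == "AGC" and res.tier == 0 and res.ay_bulge
    dv = roi.to_top(roi.orf_end_o + res.dv.start, roi.orf_end_o + res.dv.end)
    assert (dv.start, dv.end) == (anchors["dv"][0] + p, anchors["dv"][1] + p)


def test_iic_variant_accepts_cgc_triad(panels):
    rng = np.random.default_rng(43)
    iep = next(e for e in panels.iep if e.label == "C")
    construct, anchors, _ = _intron_construct(rng, iep, triad="CGC",
                                              ibs1="TTGT", ibs3="T")
    b = _Builder()
    b.add(_rand_dna(rng, 400))
    p = b.add(construct)
    b.add(_rand_dna(rng, 400))
    orf_iv = Interval("s", anchors["orf"][0] + p, anchors["orf"][1] + p, "+")
    roi = Roi(b.seq(), orf_iv, IntronConfig(), seq_id="s")
    res = find_three_prime_end(roi, intron_class="IIC")
    assert res is not None and res.triad == "CGC"
    assert roi.pos_to_top(res.three_o) == anchors["three"] + p


def test_relaxed_terminus_tiers(planted):
    roi, anchors, p = planted["roi"], planted["anchors"], planted["offset"]
    # destroy the planted AXX(X)XRAY terminus and scrub the downstream
    # window of A residues: no consensus or AY 2-mer can match
    seq = list(planted["seq"])
    start = anchors["three"] + p - 7
    tail = min(len(seq), start + 420) - start
    seq[start:start + tail] = "G" * tail
    orf_iv = Interval("s", anchors["orf"][0] + p, anchors["orf"][1] + p, "+")
    strict_cfg = IntronConfig(terminus_relax="strict")
    ay_cfg = IntronConfig(terminus_relax="ay")
    any_cfg = IntronConfig(terminus_relax="any")
    roi_mut = Roi("".join(seq), orf_iv, strict_cfg, seq_id="s")
    assert find_three_prime_end(roi_mut, strict_cfg) is None
    res_ay = find_three_prime_end(roi_mut, ay_cfg)
    res_any = find_three_prime_end(roi_mut, any_cfg)
    assert res_ay is None or res_ay.tier >= 1
    assert res_any is not None and res_any.tier >= 1  # accepted, flagged


def test_five_prime_end_exact_and_deviant(planted):
    roi, anchors, p = planted["roi"], planted["anchors"], planted["offset"]
    res = find_five_prime_end(roi)
    assert res is not None and res.mismatches == 0
    assert roi.pos_to_top(res.five_o) == anchors["five"] + p
    # deviant boundary UUGCG: one mismatch, found and flagged
    seq = list(planted["seq"])
    assert seq[p] == "G"
    seq[p] = "T"
    orf_iv = Interval("s", anchors["orf"][0] + p, anchors["orf"][1] + p, "+")
    roi_mut = Roi("".join(seq), orf_iv, IntronConfig(), seq_id="s")
    res2 = find_five_prime_end(roi_mut)
    assert res2 is not None and res2.mismatches == 1
    assert roi_mut.pos_to_top(res2.five_o) == anchors["five"] + p


def test_five_prime_end_absent_after_deletion(planted):
    anchors, p = planted["anchors"], planted["offset"]
    # delete boundary + DI region entirely
    cut = anchors["di_partner"][1] + p
    seq = planted["seq"][cut:]
    shift = -cut
    orf_iv = Interval("s", anchors["orf"][0] + p + shift,
                      anchors["orf"][1] + p + shift, "+")
    roi = Roi(seq, orf_iv, IntronConfig(), seq_id="s")
    assert find_five_prime_end(roi) is None


def test_div_basal_stem_exact_and_distance_rule(planted):
    roi, anchors, p = planted["roi"], planted["anchors"], planted["offset"]
    res = find_three_prime_end(roi, intron_class="IIB")
    dv_lo = roi.orf_end_o + res.dv.start
    basal = find_div_basal_stem(roi, dv_lo)
    assert basal is not None
    (pr0, pr1), (q0, q1) = basal
    assert (roi.to_top(q0, q1).start, roi.to_top(q0, q1).end) == \
        (anchors["basal_partner"][0] + p, anchors["basal_partner"][1] + p)
    # the partner placed > 200 bp upstream of the ORF start is out of reach
    probe = planted["seq"][roi.pos_to_top(dv_lo) - 8:roi.pos_to_top(dv_lo)]
    rng = np.random.default_rng(47)
    far = _rand_dna(rng, 260) + "TAAATG" + back_translate("M" * 150) + "TAA"
    far = _rc(probe) + far + _rand_dna(rng, 8) + probe + _rand_dna(rng, 60)
    orfs = find_orfs(far, min_len=150, seq_id="f")
    orf = next(o for o in orfs if o.strand == "+" and o.has_start)
    roi_far = Roi(far, orf.interval, IntronConfig(), seq_id="f")
    dv_far = roi_far.orf_end_o + 8 + 2
    assert find_div_basal_stem(roi_far, roi_far.orf_end_o + 8) is None


def test_map_ebs_ibs_planted_iib(planted):
    roi, anchors, p = planted["roi"], planted["anchors"], planted["offset"]
    three = find_three_prime_end(roi, intron_class="IIB")
    five = find_five_prime_end(roi)
    tgt = map_ebs_ibs(roi, five.five_o, three.three_o, "IIB")
    assert tgt.computable
    assert tgt.ibs1 == "TCATGG" and tgt.ibs1_len == 6
    assert tgt.ibs1_mismatches == 0 and tgt.ibs2_mismatches == 0
    assert (tgt.ebs1.start, tgt.ebs1.end) == (anchors["ebs1"][0] + p,
                                              anchors["ebs1"][1] + p)
    assert (tgt.ebs2.start, tgt.ebs2.end) == (anchors["ebs2"][0] + p,
                                              anchors["ebs2"][1] + p)
    assert tgt.ebs3_match is True


def test_map_ebs_ibs_iic_length_and_missing_ibs2(planted):
    roi = planted["roi"]
    three = find_three_prime_end(roi, intron_class="IIB")
    five = find_five_prime_end(roi)
    tgt = map_ebs_ibs(roi, five.five_o, three.three_o, "IIC")
    assert tgt.ibs1_len == 4
    assert tgt.ibs2 is None and tgt.ebs2 is None


def test_map_ebs_ibs_absent_ebs3_flagged(planted):
    # flip the planted EBS3 base: the expected pairing partner is missing
    roi, anchors, p = planted["roi"], planted["anchors"], planted["offset"]
    seq = list(planted["seq"])
    pos = anchors["ebs3"][0] + p
    seq[pos] = "C" if seq[pos] != "C" else "A"
    orf_iv = Interval("s", anchors["orf"][0] + p, anchors["orf"][1] + p, "+")
    roi_mut = Roi("".join(seq), orf_iv, IntronConfig(), seq_id="s")
    three = find_three_prime_end(roi_mut, intron_class="IIB")
    five = find_five_prime_end(roi_mut)
    tgt = map_ebs_ibs(roi_mut, five.five_o, three.three_o, "IIB")
    assert tgt.ebs3_match is False


# ---------------------------------------------------------------------------
# context flags and integrity (via the shared study landscape)
# ---------------------------------------------------------------------------

def _model_by_kind(report, truth, kind):
    feat = truth.by_kind(kind)[0]
    for hit, model, _ in report.introns:
        if model.three_prime == feat.anchors["three"]:
            return hit, model
    raise AssertionError(f"no model for {kind}")


def test_iic_attc_context_flags(landscape1, report1):
    _, truth = landscape1
    _, model = _model_by_kind(report1, truth, "iic_attc_intron")
    ctx = model.context
    assert ctx.inside_attc_bs and ctx.ttgtt_junction and ctx.orientation_opposite
    assert model.intron_class == "IIC" and model.integrity == "full"


def test_iib_downstream_of_attc_context_flags(landscape1, report1):
    _, truth = landscape1
    _, model = _model_by_kind(report1, truth, "iib_intron")
    ctx = model.context
    assert ctx.attc_adjacent
    assert not ctx.ttgtt_junction and not ctx.orientation_opposite
    assert model.intron_class == "IIB" and model.integrity == "full"


def test_intron_far_from_attc_has_no_context_flags(landscape1, report1):
    _, truth = landscape1
    _, model = _model_by_kind(report1, truth, "iib_intron")
    ctx = check_iic_attc_context(model, [], "+", landscape1[0])
    assert not ctx.attc_adjacent and not ctx.inside_attc_bs


def test_truncated_intron_integrity(landscape1, report1):
    _, truth = landscape1
    hit, model = _model_by_kind(report1, truth, "truncated_intron")
    assert model.five_prime is None
    assert model.integrity == "five_prime_truncated"
    assert hit.domain_coverage["RT0"] == "absent"


def test_excised_sequences_follow_coding_orientation(landscape1, report1):
    from mobscan.introns import excised_sequences
    seq, truth = landscape1
    _, model = _model_by_kind(report1, truth, "iic_attc_intron")
    parts = excised_sequences(seq, model)
    assert parts["intron"].startswith("GTGCG")
    assert parts["exon5"].endswith("TTGT")      # IIC target site, 5' exon side
    assert parts["exon3"].startswith("T")
    assert len(parts["intron"]) == model.interval.length


def test_integrity_fragmented_on_frame_disruption(panels):
    ref = panels.iep[0]
    half = len(ref.protein) // 2
    parts = [_orf_record(ref.protein[:half], start=0),
             _orf_record(ref.protein[half:], start=3 * half + 40)]
    hit = detect_iep(parts, panels.iep)[0]
    model = IntronModel(seq_id="s", strand="+", five_prime=10,
                        three_prime=2000, interval=Interval("s", 10, 2000))
    assert call_integrity(model, hit) == "fragmented"
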