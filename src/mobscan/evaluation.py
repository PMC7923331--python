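"""Closed-loop evaluation of pipeline output against planted truth.

A planted feature counts as recovered only when the detector reproduces
its anchors exactly (site and box coordinates, intron boundaries and
helix spans, EBS windows, IS element ends) and the derived calls
(classification, integrity, context flags) match the planted state.
"""

from __future__ import annotations

from dataclasses import dataclass

from .panels import ReferencePanels
from .pipeline import PipelineConfig, SequenceReport, annotate_sequence
from .seq_core import GenomicSequence
from .synthetic import SyntheticTruth, TruthFeature


@dataclass
class RecoveryResult:
    per_kind: dict[str, tuple[int, int]]   # kind -> (recovered, planted)
    failures: list[str]

    @property
    def recovered(self) -> int:
        return sum(r for r, _ in self.per_kind.values())

    @property
    def planted(self) -> int:
        return sum(n for _, n in self.per_kind.values())

    @property
    def fraction(self) -> float:
        return self.recovered / self.planted if self.planted else 1.0


def _anchors_iv(f: TruthFeature, name: str) -> tuple[int, int]:
    v = f.anchors[name]
    return (v[0], v[1])


def _match_attc(f: TruthFeature, report: SequenceReport) -> bool:
    for s in report.sites:
        if ((s.interval.start, s.interval.end) == f.interval
                and s.strand == f.strand
                and (s.box_r2.start, s.box_r2.end) == _anchors_iv(f, "r2")
                and (s.box_l2.start, s.box_l2.end) == _anchors_iv(f, "l2")
                and (s.box_l1.start, s.box_l1.end) == _anchors_iv(f, "l1")
                and (s.box_r1.start, s.box_r1.end) == _anchors_iv(f, "r1")):
            return True
    return False


def _match_inti(f: TruthFeature, report: SequenceReport) -> bool:
    for locus in report.loci:
        if locus.classification != "complete_integron" or locus.intI_hit is None:
            continue
        iv = locus.intI_hit[0]
        if (iv.start, iv.end) == f.interval and iv.strand == f.strand:
            return True
    return False


def _match_cassette_orf(f: TruthFeature, report: SequenceReport) -> bool:
    for locus in report.loci:
        for cass in locus.cassettes:
            for orf in cass.orfs:
                if ((orf.interval.start, orf.interval.end) == f.interval
                        and orf.strand == f.strand):
                    return True
    return False


def _models_for(f: TruthFeature, report: SequenceReport):
    for hit, model, locus_idx in report.introns:
        yield hit, model, locus_idx


def _match_intron(f: TruthFeature, report: SequenceReport) -> bool:
    for hit, model, _ in _models_for(f, report):
        if model.strand != f.strand:
            continue
        if model.three_prime is None:
            continue
        if model.dv_interval is None or model.dvi_interval is None:
            continue
        if ((model.dv_interval.start, model.dv_interval.end)
                != _anchors_iv(f, "dv")):
            continue
        if ((model.dvi_interval.start, model.dvi_interval.end)
                != _anchors_iv(f, "dvi")):
            continue
        if model.three_prime != f.anchors["three"]:
            continue
        if f.kind == "truncated_intron":
            if (model.five_prime is None
                    and model.integrity == "five_prime_truncated"):
                return True
            continue
        if model.five_prime != f.anchors["five"]:
            continue
        if model.integrity != "full":
            continue
        ctx = model.context
        if f.kind == "iic_attc_intron":
            if (model.intron_class == "IIC" and ctx is not None
                    and ctx.inside_attc_bs and ctx.ttgtt_junction
                    and ctx.orientation_opposite
                    and model.target is not None
                    and model.target.ibs1_len == 4
                    and model.target.ibs2 is None):
                return True
        elif f.kind == "iib_intron":
            tgt = model.target
            if (model.intron_class == "IIB" and tgt is not None
                    and tgt.ebs1 is not None and tgt.ebs2 is not None
                    and (tgt.ebs1.start, tgt.ebs1.end) == _anchors_iv(f, "ebs1")
                    and (tgt.ebs2.start, tgt.ebs2.end) == _anchors_iv(f, "ebs2")
                    and tgt.ebs3_match is True
                    and ctx is not None and ctx.attc_adjacent
                    and not ctx.ttgtt_junction
                    and not ctx.orientation_opposite):
                return True
    return False


def _match_is(f: TruthFeature, report: SequenceReport) -> bool:
    for e, _ in report.is_elements:
        if (e.interval.start, e.interval.end) != f.interval:
            continue
        if e.group_call != "IS605_group":
            continue
        if e.configuration != "opposite_orientation":
            continue
        if e.tnpA is None or e.tnpB is None:
            continue
        a = e.tnpA.orf.interval
        b = e.tnpB.orf.interval
        if ((a.start, a.end) == _anchors_iv(f, "tnpA")
                and (b.start, b.end) == _anchors_iv(f, "tnpB")):
            return True
    return False


_MATCHERS = {
    "attc_site": _match_attc,
    "intI_gene": _match_inti,
    "cassette_orf": _match_cassette_orf,
    "ta_toxin": _match_cassette_orf,
    "ta_antitoxin": _match_cassette_orf,
    "iic_attc_intron": _match_intron,
    "iib_intron": _match_intron,
    "truncated_intron": _match_intron,
    "is605_element": _match_is,
}


def evaluate_report(truth: SyntheticTruth, report: SequenceReport) -> RecoveryResult:
    per_kind: dict[str, list[int]] = {}
    failures: list[str] = []
    for f in truth.features:
        matcher = _MATCHERS.get(f.kind)
        if matcher is None:
            continue
        rec = per_kind.setdefault(f.kind, [0, 0])
        rec[1] += 1
        if matcher(f, report):
            rec[0] += 1
        else:
            failures.append(f"{f.kind}@{f.start}-{f.end}{f.strand}")
    return RecoveryResult(
        per_kind={k: (v[0], v[1]) for k, v in per_kind.items()},
        failures=failures)


def evaluate_landscape(seq: GenomicSequence, truth: SyntheticTruth,
                       panels: ReferencePanels | None = None,
                       config: PipelineConfig | None = None) -> RecoveryResult:
    """Run the full pipeline on a synthetic landscape and score recovery."""
    panels = panels or ReferencePanels.default()
    report = annotate_sequence(seq, panels, config or PipelineConfig())
    return evaluate_report(truth, report)
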