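"""End-to-end annotation pipeline.

Stage order mirrors the analysis workflow: attC detection and clustering
into integron loci / CALINs -> ORF annotation and cassette delineation ->
intI classification -> IEP detection -> intron boundary/structure
inference -> IS200/605 detection -> replication-strand context.  Outputs
are a machine-readable run report (JSON) and GFF3.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field

import yaml

from . import __version__
from .attc import (AttCConfig, AttCSite, IntegronLocus, classify_locus,
                   cluster_attc, delineate_cassettes, scan_attc)
from .errors import ConfigurationError
from .gff import GFFFeature, write_gff3
from .introns import IEPHit, IntronConfig, IntronModel, annotate_intron, detect_iep
from .is_elements import ISConfig, ISElement, find_is_elements
from .panels import ReferencePanels
from .replication import ReplicationContext, assign_strand
from .seq_core import GenomicSequence, Interval, ORFRecord, find_orfs

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with documented defaults."""

    orf_min_len: int = 150
    cluster_threshold_bp: int = 8000
    leader_bp: int = 2000
    inti_window_bp: int = 10000
    inti_min_identity: float = 35.0
    inti_min_coverage: float = 0.7
    link_distance_bp: int = 2000
    enable_attc: bool = True
    enable_introns: bool = True
    enable_is: bool = True
    oric_start: int | None = None     # 1-based inclusive, as printed
    oric_end: int | None = None
    attc: AttCConfig = field(default_factory=AttCConfig)
    intron: IntronConfig = field(default_factory=IntronConfig)
    is_config: ISConfig = field(default_factory=ISConfig)

    def to_flat_dict(self) -> dict:
        flat = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                for g in dataclasses.fields(v):
                    val = getattr(v, g.name)
                    flat[f"{f.name}.{g.name}"] = (list(val) if isinstance(val, tuple)
                                                  else val)
            else:
                flat[f.name] = v
        return flat

    @classmethod
    def from_flat_dict(cls, flat: dict) -> "PipelineConfig":
        cfg = cls()
        subs = {"attc": cfg.attc, "intron": cfg.intron, "is_config": cfg.is_config}
        valid_top = {f.name for f in dataclasses.fields(cls)}
        for key, value in (flat or {}).items():
            if "." in key:
                group, name = key.split(".", 1)
                if group not in subs or not hasattr(subs[group], name):
                    raise ConfigurationError(f"unknown config key {key!r}")
                current = getattr(subs[group], name)
                if isinstance(current, tuple):
                    value = tuple(value)
                setattr(subs[group], name, value)
            else:
                if key not in valid_top:
                    raise ConfigurationError(f"unknown config key {key!r}")
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_flat_dict(yaml.safe_load(fh) or {})

    def dump_yaml(self) -> str:
        return yaml.safe_dump(self.to_flat_dict(), sort_keys=True)


@dataclass
class SequenceReport:
    seq_id: str
    length: int
    orfs: list[ORFRecord]
    sites: list[AttCSite]
    loci: list[IntegronLocus]
    introns: list[tuple[IEPHit, IntronModel, int | None]]  # locus index or None
    is_elements: list[tuple[ISElement, int | None]]
    strand_calls: list[dict]

    @property
    def summary(self) -> dict:
        return {
            "n_orfs": len(self.orfs),
            "n_attc_sites": len(self.sites),
            "n_loci": len(self.loci),
            "n_complete_integrons": sum(
                1 for l in self.loci if l.classification == "complete_integron"),
            "n_calins": sum(1 for l in self.loci if l.classification == "CALIN"),
            "n_introns": len(self.introns),
            "n_is_elements": len(self.is_elements),
        }


@dataclass
class RunReport:
    header: dict
    sequences: list[SequenceReport]

    @property
    def summary(self) -> dict:
        totals: dict[str, int] = {}
        for sr in self.sequences:
            for k, v in sr.summary.items():
                totals[k] = totals.get(k, 0) + v
        return totals


def _cassette_strand(locus: IntegronLocus) -> str | None:
    """Cassette transcription polarity of a locus: the majority coding
    orientation of its attC sites (an attC sits at the 3' end of its
    cassette, so site orientation defines array polarity)."""
    plus = sum(1 for s in locus.sites if s.strand == "+")
    minus = len(locus.sites) - plus
    if plus == minus:
        return None
    return "+" if plus > minus else "-"


def _locus_for(interval: Interval, loci: list[IntegronLocus],
               link_bp: int) -> int | None:
    mid = interval.midpoint
    best = None
    for i, locus in enumerate(loci):
        iv = locus.interval
        dist = max(iv.start - mid, mid - iv.end, 0)
        if dist <= link_bp and (best is None or dist < best[0]):
            best = (dist, i)
    return best[1] if best else None


def annotate_sequence(seq: GenomicSequence, panels: ReferencePanels,
                      config: PipelineConfig | None = None) -> SequenceReport:
    cfg = config or PipelineConfig()
    t0 = time.monotonic()
    orfs = find_orfs(seq, min_len=cfg.orf_min_len)
    logger.info("%s: %d ORFs (%.1fs)", seq.id, len(orfs), time.monotonic() - t0)

    sites: list[AttCSite] = []
    loci: list[IntegronLocus] = []
    if cfg.enable_attc:
        t0 = time.monotonic()
        sites = scan_attc(seq, cfg.attc)
        loci = cluster_attc(sites, threshold_bp=cfg.cluster_threshold_bp)
        for locus in loci:
            delineate_cassettes(locus, orfs, leader_bp=cfg.leader_bp)
            classify_locus(seq, locus, panels.inti, orfs,
                           window_bp=cfg.inti_window_bp,
                           min_identity=cfg.inti_min_identity,
                           min_coverage=cfg.inti_min_coverage)
        logger.info("%s: %d attC sites, %d loci (%.1fs)", seq.id, len(sites),
                    len(loci), time.monotonic() - t0)

    introns: list[tuple[IEPHit, IntronModel, int | None]] = []
    if cfg.enable_introns:
        t0 = time.monotonic()
        hits = detect_iep(orfs, panels.iep, cfg.intron)
        for hit in hits:
            locus_idx = _locus_for(hit.interval, loci, cfg.link_distance_bp)
            cassette_strand = None
            if locus_idx is not None:
                cassette_strand = _cassette_strand(loci[locus_idx])
            model = annotate_intron(seq, hit, panels.iep, cfg.intron,
                                    attc_sites=sites,
                                    cassette_strand=cassette_strand)
            introns.append((hit, model, locus_idx))
        logger.info("%s: %d IEP hits (%.1fs)", seq.id, len(hits),
                    time.monotonic() - t0)

    elements: list[tuple[ISElement, int | None]] = []
    if cfg.enable_is:
        t0 = time.monotonic()
        for element in find_is_elements(seq, panels.tnp, cfg.is_config,
                                        orfs=orfs):
            elements.append((element,
                             _locus_for(element.interval, loci,
                                        cfg.link_distance_bp)))
        logger.info("%s: %d IS elements (%.1fs)", seq.id, len(elements),
                    time.monotonic() - t0)

    strand_calls: list[dict] = []
    if cfg.oric_start is not None and cfg.oric_end is not None:
        ctx = ReplicationContext.from_oric(
            seq.length, cfg.oric_start - 1, cfg.oric_end, seq_id=seq.id)
        named: list[tuple[str, Interval]] = []
        for locus in loci:
            for site in locus.sites:
                named.append(("attc_bs",
                              Interval(seq.id, site.interval.start,
                                       site.interval.end, site.bs_strand)))
        for hit, model, _ in introns:
            named.append(("intron_iep", hit.interval))
        for element, _ in elements:
            if element.tnpA:
                named.append(("tnpA", element.tnpA.orf.interval))
        for name, iv in named:
            call = assign_strand(ctx, iv)
            strand_calls.append({
                "feature": name, "start": iv.start, "end": iv.end,
                "strand": iv.strand, "role": call.role,
                "replichore": call.replichore, "spans_ter": call.spans_ter})

    return SequenceReport(seq_id=seq.id, length=seq.length, orfs=orfs,
                          sites=sites, loci=loci, introns=introns,
                          is_elements=elements, strand_calls=strand_calls)


def run(seqs: list[GenomicSequence], panels: ReferencePanels,
        config: PipelineConfig | None = None) -> RunReport:
    cfg = config or PipelineConfig()
    panels.validate()
    header = {
        "tool": "mobscan",
        "version": __version__,
        "generated_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": cfg.to_flat_dict(),
    }
    return RunReport(header=header,
                     sequences=[annotate_sequence(s, panels, cfg) for s in seqs])


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _iv(iv: Interval | None) -> list | None:
    return None if iv is None else [iv.start, iv.end, iv.strand]


def _site_dict(s: AttCSite) -> dict:
    return {"interval": _iv(s.interval), "strand": s.strand,
            "bs_strand": s.bs_strand,
            "boxes": {"R2": _iv(s.box_r2), "L2": _iv(s.box_l2),
                      "L1": _iv(s.box_l1), "R1": _iv(s.box_r1)},
            "r_pairing": round(s.r_pairing, 4),
            "l_pairing": round(s.l_pairing, 4),
            "fold_score": s.fold_score}


def _orf_dict(o: ORFRecord) -> dict:
    return {"interval": _iv(o.interval), "has_start": o.has_start,
            "has_stop": o.has_stop, "protein_length": len(o.protein)}


def _locus_dict(locus: IntegronLocus) -> dict:
    return {
        "interval": _iv(locus.interval),
        "classification": locus.classification,
        "intI": (None if locus.intI_hit is None else
                 {"interval": _iv(locus.intI_hit[0]),
                  "identity": round(locus.intI_hit[1], 2)}),
        "sites": [_site_dict(s) for s in locus.sites],
        "cassettes": [
            {"interval": _iv(c.interval),
             "upstream_attc": c.upstream_attc,
             "downstream_attc": c.downstream_attc,
             "orfs": [_orf_dict(o) for o in c.orfs],
             "boundary_spanning": c.boundary_spanning}
            for c in locus.cassettes],
    }


def _intron_dict(hit: IEPHit, model: IntronModel, locus_idx: int | None) -> dict:
    target = model.target
    return {
        "iep": {
            "interval": _iv(hit.interval),
            "best_ref": hit.best_ref.id,
            "class": hit.best_ref.label,
            "identity": round(hit.identity, 2),
            "similarity": round(hit.similarity, 2),
            "domains": hit.domain_coverage,
            "yadd": hit.yadd,
            "frame_disruptions": hit.frame_disruptions,
        },
        "model": {
            "strand": model.strand,
            "five_prime": model.five_prime,
            "three_prime": model.three_prime,
            "interval": _iv(model.interval),
            "dv": _iv(model.dv_interval),
            "dvi": _iv(model.dvi_interval),
            "dv_triad": model.dv_triad,
            "dv_ay_bulge": model.dv_ay_bulge,
            "div_basal_stem": (None if model.div_basal_stem is None else
                               [_iv(model.div_basal_stem[0]),
                                _iv(model.div_basal_stem[1])]),
            "ebs": {k: _iv(v) for k, v in model.ebs.items()},
            "target_site": (None if target is None else {
                "computable": target.computable,
                "ibs1": target.ibs1, "ibs1_len": target.ibs1_len,
                "ibs1_mismatches": target.ibs1_mismatches,
                "ibs2": target.ibs2,
                "ibs2_mismatches": target.ibs2_mismatches,
                "ebs3_match": target.ebs3_match,
            }),
            "context": (None if model.context is None else dataclasses.asdict(model.context)),
            "iep_class": model.iep_class,
            "intron_class": model.intron_class,
            "integrity": model.integrity,
            "deviations": model.deviations,
        },
        "locus": locus_idx,
    }


def _element_dict(e: ISElement, locus_idx: int | None) -> dict:
    def end_dict(h):
        return None if h is None else {"interval": [h.start, h.end],
                                       "stem_pairs": h.stem_pairs,
                                       "loop_len": h.loop_len}
    def gene_dict(g):
        return None if g is None else {"interval": _iv(g.orf.interval),
                                       "ref": g.ref.id,
                                       "identity": round(g.identity, 2)}
    return {"interval": _iv(e.interval), "configuration": e.configuration,
            "group_call": e.group_call, "tnpA": gene_dict(e.tnpA),
            "tnpB": gene_dict(e.tnpB), "left_end": end_dict(e.left_end),
            "right_end": end_dict(e.right_end), "locus": locus_idx}


def report_to_dict(report: RunReport) -> dict:
    return {
        "header": report.header,
        "summary": report.summary,
        "sequences": [
            {"id": sr.seq_id, "length": sr.length, "summary": sr.summary,
             "attc_sites": [_site_dict(s) for s in sr.sites],
             "loci": [_locus_dict(l) for l in sr.loci],
             "introns": [_intron_dict(h, m, li) for h, m, li in sr.introns],
             "is_elements": [_element_dict(e, li) for e, li in sr.is_elements],
             "replication": sr.strand_calls}
            for sr in report.sequences],
    }


def write_report_json(path, report: RunReport) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=1, sort_keys=True)
        fh.write("\n")


def report_to_gff_features(report: RunReport) -> list[GFFFeature]:
    feats: list[GFFFeature] = []
    for sr in report.sequences:
        sid = sr.seq_id
        for i, s in enumerate(sr.sites):
            aid = f"attc{i}"
            feats.append(GFFFeature(sid, "attC", s.interval.start,
                                    s.interval.end, s.strand,
                                    attributes={"ID": aid}))
            for name, box in (("R2", s.box_r2), ("L2", s.box_l2),
                              ("L1", s.box_l1), ("R1", s.box_r1)):
                feats.append(GFFFeature(sid, "attC_box", box.start, box.end,
                                        s.strand,
                                        attributes={"Parent": aid, "Name": name}))
        for i, locus in enumerate(sr.loci):
            kind = ("integron" if locus.classification == "complete_integron"
                    else "CALIN")
            lid = f"locus{i}"
            feats.append(GFFFeature(sid, kind, locus.interval.start,
                                    locus.interval.end, ".",
                                    attributes={"ID": lid}))
            for j, cass in enumerate(locus.cassettes):
                feats.append(GFFFeature(sid, "gene_cassette",
                                        cass.interval.start, cass.interval.end,
                                        ".", attributes={"ID": f"{lid}.cassette{j}",
                                                         "Parent": lid}))
        for i, (hit, model, _) in enumerate(sr.introns):
            gid = f"intron{i}"
            span = model.interval or hit.interval
            feats.append(GFFFeature(sid, "group_II_intron", span.start, span.end,
                                    model.strand,
                                    attributes={"ID": gid,
                                                "integrity": model.integrity,
                                                "intron_class": model.intron_class}))
            for name, iv in (("DV", model.dv_interval), ("DVI", model.dvi_interval)):
                if iv is not None:
                    feats.append(GFFFeature(sid, "intron_domain", iv.start, iv.end,
                                            model.strand,
                                            attributes={"Parent": gid, "Name": name}))
            for name, iv in model.ebs.items():
                feats.append(GFFFeature(sid, "exon_binding_site", iv.start, iv.end,
                                        model.strand,
                                        attributes={"Parent": gid, "Name": name}))
        for i, (e, _) in enumerate(sr.is_elements):
            eid = f"is{i}"
            feats.append(GFFFeature(sid, "insertion_sequence", e.interval.start,
                                    e.interval.end, ".",
                                    attributes={"ID": eid,
                                                "group_call": e.group_call}))
            for name, gene in (("tnpA", e.tnpA), ("tnpB", e.tnpB)):
                if gene is not None:
                    feats.append(GFFFeature(sid, "CDS", gene.orf.interval.start,
                                            gene.orf.interval.end,
                                            gene.orf.strand,
                                            attributes={"Parent": eid, "Name": name}))
            for name, h in (("left_end", e.left_end), ("right_end", e.right_end)):
                if h is not None:
                    feats.append(GFFFeature(sid, "hairpin", h.start, h.end, ".",
                                            attributes={"Parent": eid, "Name": name}))
    return feats


def write_report_gff(path, report: RunReport) -> None:
    lengths = {sr.seq_id: sr.length for sr in report.sequences}
    write_gff3(path, report_to_gff_features(report), seq_lengths=lengths)
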