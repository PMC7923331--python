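"""Group II intron annotation.

Detects intron-encoded proteins (IEPs) by panel homology, infers the
ribozyme's 3' end from the conserved DV/DVI helix pair and the 3' boundary
consensus AXX(X)XRAY, the 5' end from the GUGYG boundary consensus anchored
by a DI basal duplex, the DIV basal stem, and the EBS-IBS target pairing;
classifies introns by nearest reference class and calls integrity
(full / 5'-truncated / fragmented).

All structural work happens in an intron-oriented region of interest (ROI)
around the IEP ORF, so one code path serves both strands; coordinates are
converted back to top-strand intervals at the end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import align as _align
from .errors import ConfigurationError
from .panels import PanelEntry, RIBOZYME_CLASS
from .rna_structure import (Hairpin, best_antiparallel_duplex, can_pair,
                            find_stem_loops)
from .seq_core import GenomicSequence, Interval, ORFRecord, iupac_scan, residues_of, revcomp

DOMAIN_NAMES = ("RT0", "RT1", "RT2", "RT3", "RT4", "RT5", "RT6", "RT7", "X", "En")
RT_CORE = ("RT0", "RT1", "RT2", "RT3", "RT4", "RT5", "RT6", "RT7")

FIVE_PRIME_CONSENSUS = "GTGYG"          # GUGYG on the RNA
# 3' boundary consensus AXX(X)XRAY: A, 3-4 any, R, A, Y (7 or 8 nt)
_TERMINUS_RE = re.compile(r"A[ACGT]{3,4}[AG]A[CT]")
_AY_RE = re.compile(r"A[CT]")


@dataclass
class IntronConfig:
    """Windows and budgets for boundary/structure inference."""

    three_prime_window: int = 400        # bp downstream of the IEP ORF
    five_prime_window: int = 3000        # bp upstream of the IEP ORF
    gugyg_max_mismatch: int = 1
    di_probe_len: int = 12               # DI basal duplex probe after GUGYG
    di_search_bp: int = 300
    min_di_pairs: int = 11               # acceptance threshold for the duplex
    dv_min_stem: int = 5
    dv_loop_range: tuple[int, int] = (3, 12)
    dv_max_bulge: int = 2
    dv_max_offset: int = 60              # DV must start near the ORF end
    max_dv_dvi_gap: int = 30
    terminus_window: int = 20
    terminus_relax: str = "ay"           # "strict" | "ay" | "any"
    basal_probe_len: int = 8
    basal_upstream_bp: int = 200
    basal_min_pairs: int = 7             # probe_len - 1 mismatch
    ebs_search_bp: int = 600
    ebs_max_mismatch: int = 1
    iep_min_identity: float = 30.0
    iep_merge_gap: int = 1000
    domain_present_frac: float = 0.7
    domain_partial_frac: float = 0.15
    class_margin: float = 5.0


@dataclass
class IEPHit:
    """An intron-encoded protein call, possibly merged from several ORF
    fragments of one disrupted reading frame."""

    parts: list[tuple[ORFRecord, _align.AlignmentStats, PanelEntry]]
    interval: Interval
    best_ref: PanelEntry
    identity: float
    similarity: float
    domain_coverage: dict[str, str]      # domain -> present|partial|absent
    yadd: str                            # "present" | "absent"
    frame_disruptions: int

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def protein(self) -> str:
        return self.parts[0][0].protein

    def domain_status(self, name: str) -> str:
        return self.domain_coverage.get(name, "absent")


@dataclass
class TargetSiteReport:
    """EBS-IBS pairing between the intron's DI and the flanking exons."""

    computable: bool
    ibs1: str | None = None
    ibs1_len: int = 0
    ibs1_mismatches: int | None = None
    ebs1: Interval | None = None
    ibs2: str | None = None
    ibs2_mismatches: int | None = None
    ebs2: Interval | None = None
    ebs3: Interval | None = None
    ebs3_match: bool | None = None
    upstream_hairpin: Hairpin | None = None


@dataclass
class ContextFlags:
    """IIC-attC insertion-context flags."""

    attc_adjacent: bool = False          # an attC within the adjacency window
    inside_attc_bs: bool = False         # junction within/immediately at a site
    ttgtt_junction: bool = False         # exon junction matches TTGT/T
    orientation_opposite: bool = False   # intron vs cassette transcription


@dataclass
class IntronModel:
    """Inferred ribozyme model for one IEP locus."""

    seq_id: str
    strand: str
    five_prime: int | None               # top-strand coord of the 5' boundary edge
    three_prime: int | None              # top-strand coord of the 3' boundary edge
    interval: Interval | None            # full span when both boundaries resolved
    dv: Hairpin | None = None            # ROI-local; top-strand via dv_interval
    dvi: Hairpin | None = None
    dv_interval: Interval | None = None
    dvi_interval: Interval | None = None
    dv_triad: str = "other"
    dv_ay_bulge: bool = False
    dvi_bulged_a: int | None = None      # top-strand position
    div_basal_stem: tuple[Interval, Interval] | None = None
    ebs: dict[str, Interval] = field(default_factory=dict)
    target: TargetSiteReport | None = None
    context: ContextFlags | None = None
    intron_class: str = "unclassified"   # ribozyme class: IIA/IIB/IIC/...
    iep_class: str = "unclassified"      # IEP class: ML/CL1/.../ambiguous
    integrity: str = "fragmented"
    deviations: list[str] = field(default_factory=list)


class Roi:
    """Intron-oriented window around an IEP ORF with coordinate transforms."""

    def __init__(self, seq: GenomicSequence | str, hit_interval: Interval,
                 cfg: IntronConfig, seq_id: str | None = None):
        res = residues_of(seq)
        self.seq_id = seq_id or (seq.id if isinstance(seq, GenomicSequence) else "seq")
        self.strand = hit_interval.strand
        L = len(res)
        pad5 = cfg.five_prime_window + 1200
        pad3 = cfg.three_prime_window + 200
        if self.strand == "+":
            self.top_start = max(0, hit_interval.start - pad5)
            self.top_end = min(L, hit_interval.end + pad3)
            self.oriented = res[self.top_start:self.top_end]
            self.orf_start_o = hit_interval.start - self.top_start
            self.orf_end_o = hit_interval.end - self.top_start
        else:
            self.top_start = max(0, hit_interval.start - pad3)
            self.top_end = min(L, hit_interval.end + pad5)
            self.oriented = revcomp(res[self.top_start:self.top_end])
            self.orf_start_o = self.top_end - hit_interval.end
            self.orf_end_o = self.top_end - hit_interval.start

    def to_top(self, s: int, e: int) -> Interval:
        if self.strand == "+":
            return Interval(self.seq_id, self.top_start + s, self.top_start + e,
                            self.strand)
        return Interval(self.seq_id, self.top_end - e, self.top_end - s,
                        self.strand)

    def pos_to_top(self, p: int) -> int:
        return self.top_start + p if self.strand == "+" else self.top_end - p


# ---------------------------------------------------------------------------
# IEP detection
# ---------------------------------------------------------------------------

def detect_iep(orfs: list[ORFRecord], iep_refs: list[PanelEntry],
               cfg: IntronConfig | None = None) -> list[IEPHit]:
    """Match ORFs to the labeled IEP panel and project domain coverage.

    ORF fragments of one disrupted frame (same strand, same reference class,
    within the merge gap) are merged into a single hit whose
    ``frame_disruptions`` counts the joins.
    """
    cfg = cfg or IntronConfig()
    if not iep_refs:
        raise ConfigurationError("IEP reference panel is empty")
    for ref in iep_refs:
        if not ref.domains:
            raise ConfigurationError(f"IEP panel entry {ref.id} lacks domain annotations")

    ref_kmers = [(ref, _align.kmer_set(ref.protein)) for ref in iep_refs]
    raw: list[tuple[ORFRecord, _align.AlignmentStats, PanelEntry]] = []
    for orf in orfs:
        if len(orf.protein) < 50:
            continue
        qk = _align.kmer_set(orf.protein)
        best: tuple[_align.AlignmentStats, PanelEntry] | None = None
        for ref, rk in ref_kmers:
            if not _align.shares_kmers(qk, rk):
                continue
            stats = _align.align_stats(orf.protein, ref.protein, mode="local")
            if stats is None or stats.identity < cfg.iep_min_identity:
                continue
            if stats.aligned_columns < 40:
                continue
            if best is None or stats.score > best[0].score:
                best = (stats, ref)
        if best:
            raw.append((orf, best[0], best[1]))

    raw.sort(key=lambda t: t[0].interval.start)
    groups: list[list[tuple[ORFRecord, _align.AlignmentStats, PanelEntry]]] = []
    for item in raw:
        orf, stats, ref = item
        if groups:
            p_orf, _, p_ref = groups[-1][-1]
            if (orf.strand == p_orf.strand and ref.label == p_ref.label
                    and orf.interval.start - p_orf.interval.end <= cfg.iep_merge_gap):
                groups[-1].append(item)
                continue
        groups.append([item])

    hits: list[IEPHit] = []
    for group in groups:
        main = max(group, key=lambda t: t[1].aligned_columns)
        seq_id = main[0].interval.seq_id
        start = min(t[0].interval.start for t in group)
        end = max(t[0].interval.end for t in group)
        coverage: dict[str, str] = {}
        yadd = "absent"
        for name in DOMAIN_NAMES:
            best_frac = 0.0
            for orf, stats, ref in group:
                if name not in ref.domains:
                    continue
                frac, q_iv = stats.project_ref_interval(*ref.domains[name])
                best_frac = max(best_frac, frac)
                if name == "RT5" and q_iv is not None:
                    lo, hi = q_iv
                    if "YADD" in orf.protein[max(0, lo - 2):hi + 2]:
                        yadd = "present"
            if name not in main[2].domains:
                continue
            if best_frac >= cfg.domain_present_frac:
                coverage[name] = "present"
            elif best_frac >= cfg.domain_partial_frac:
                coverage[name] = "partial"
            else:
                coverage[name] = "absent"
        hits.append(IEPHit(
            parts=group,
            interval=Interval(seq_id, start, end, main[0].strand),
            best_ref=main[2], identity=main[1].identity,
            similarity=main[1].similarity, domain_coverage=coverage,
            yadd=yadd, frame_disruptions=len(group) - 1))
    return hits


def classify_intron(iep_hit: IEPHit, iep_refs: list[PanelEntry],
                    margin: float = 5.0) -> tuple[str, dict[str, float]]:
    """Nearest-reference class call with an identity margin.

    Returns (class_label, per-class best identity).  The best class must
    beat the runner-up class by >= ``margin`` identity points, otherwise
    the call is "ambiguous".
    """
    per_class: dict[str, float] = {}
    qk = _align.kmer_set(iep_hit.protein)
    for ref in iep_refs:
        if not _align.shares_kmers(qk, _align.kmer_set(ref.protein), min_shared=1):
            continue
        stats = _align.align_stats(iep_hit.protein, ref.protein, mode="local")
        if stats is None:
            continue
        per_class[ref.label] = max(per_class.get(ref.label, 0.0), stats.identity)
    if not per_class:
        return "ambiguous", per_class
    ranked = sorted(per_class.items(), key=lambda kv: -kv[1])
    if len(ranked) == 1 or ranked[0][1] - ranked[1][1] >= margin:
        return ranked[0][0], per_class
    return "ambiguous", per_class


# ---------------------------------------------------------------------------
# Boundary / structure inference (ROI-local)
# ---------------------------------------------------------------------------

def _hairpin_bulge_positions(window: str, h: Hairpin) -> list[int]:
    paired = {i for p in h.pair_list for i in p}
    lo_in, hi_in = h.pair_list[-1]
    loop = set(range(lo_in + 1, hi_in))
    return [p for p in range(h.start, h.end) if p not in paired and p not in loop]


@dataclass
class ThreePrimeResult:
    dv: Hairpin
    dvi: Hairpin
    three_o: int                   # ROI-local boundary edge (exclusive end)
    triad: str
    ay_bulge: bool
    dvi_bulged_a: int | None       # ROI-local
    tier: int                      # 0 full consensus, 1 AY, 2 unmatched


def find_three_prime_end(roi: Roi, cfg: IntronConfig | None = None,
                         intron_class: str | None = None) -> ThreePrimeResult | None:
    """Best-scoring adjacent DV/DVI hairpin pair plus the 3' boundary.

    DV must start within ``dv_max_offset`` of the ORF end (it sits at the
    base of DIV, which carries the ORF) and carry the catalytic triad (AGC,
    or CGC for group IIC) in its 5' arm; DVI follows within a short gap and
    must carry a bulged A.  The boundary is the earliest-ending match of
    the 3' consensus AXX(X)XRAY downstream of DVI, with tiered relaxation
    (AY 2-mer, then any position) recorded as a deviation.  Candidate pairs
    are ranked by (consensus tier, combined helix score, position).
    """
    cfg = cfg or IntronConfig()
    window = roi.oriented[roi.orf_end_o: roi.orf_end_o + cfg.three_prime_window]
    hairpins = find_stem_loops(window, min_stem=cfg.dv_min_stem,
                               loop_range=cfg.dv_loop_range,
                               max_bulge=cfg.dv_max_bulge,
                               suppress_overlaps=False)
    if intron_class == "IIC":
        triads = ("CGC", "AGC")
    elif intron_class in (None, "unclassified", "ambiguous"):
        triads = ("AGC", "CGC")
    else:
        triads = ("AGC",)

    best: tuple[int, float, int, ThreePrimeResult] | None = None
    for h1 in hairpins:
        if h1.start > cfg.dv_max_offset:
            continue
        arm_hi = max(i for i, _ in h1.pair_list)
        arm_seq = window[h1.start:arm_hi + 1]
        triad = next((t for t in triads if t in arm_seq), None)
        if triad is None:
            continue
        b1 = _hairpin_bulge_positions(window, h1)
        ay = any(window[p] == "A" and p + 1 < len(window) and window[p + 1] in "CT"
                 for p in b1)
        for h2 in hairpins:
            gap = h2.start - h1.end
            if gap < 0 or gap > cfg.max_dv_dvi_gap:
                continue
            b2 = _hairpin_bulge_positions(window, h2)
            bulged_a = next((p for p in b2 if window[p] == "A"), None)
            if bulged_a is None:
                continue
            tail = window[h2.end: h2.end + cfg.terminus_window]
            end_off, tier = _match_terminus(tail, cfg.terminus_relax)
            if end_off is None:
                continue
            score = h1.score + h2.score
            res = ThreePrimeResult(
                dv=h1, dvi=h2, three_o=roi.orf_end_o + h2.end + end_off,
                triad=triad, ay_bulge=ay, dvi_bulged_a=roi.orf_end_o + bulged_a,
                tier=tier)
            key = (tier, -score, h1.start)
            if best is None or key < best[:3]:
                best = (*key, res)
    return best[3] if best else None


def _match_terminus(tail: str, relax: str) -> tuple[int | None, int]:
    """Earliest-ending 3'-consensus match in ``tail``; (end offset, tier)."""
    ends = []
    for start in range(len(tail)):
        for length in (7, 8):
            piece = tail[start:start + length]
            if len(piece) == length and _TERMINUS_RE.fullmatch(piece):
                ends.append(start + length)
    if ends:
        return min(ends), 0
    if relax in ("ay", "any"):
        m = _AY_RE.search(tail[:10])
        if m:
            return m.end(), 1
    if relax == "any":
        return (2 if len(tail) >= 2 else None), 2
    return None, -1


@dataclass
class FivePrimeResult:
    five_o: int                    # ROI-local first intron base
    mismatches: int
    di_pairs: int
    candidates: list[tuple[int, int, int]]  # (mismatches, pairs, ROI pos)


def find_five_prime_end(roi: Roi, cfg: IntronConfig | None = None) -> FivePrimeResult | None:
    """5' boundary: GUGYG match (<= budget) whose downstream region forms a
    DI basal duplex — a long-range antiparallel WC complement of the probe
    immediately following the boundary.  Candidates are ranked by
    (mismatches, duplex pairs desc, position); None when no candidate
    reaches the duplex threshold (candidate 5'-truncation)."""
    cfg = cfg or IntronConfig()
    win_start = max(0, roi.orf_start_o - cfg.five_prime_window)
    window = roi.oriented[win_start:roi.orf_start_o]
    matches = iupac_scan(FIVE_PRIME_CONSENSUS, window, cfg.gugyg_max_mismatch,
                         strands="+")
    scored: list[tuple[int, int, int]] = []
    for pos, _, mm in matches:
        p = win_start + pos
        probe_start = p + len(FIVE_PRIME_CONSENSUS)
        probe = roi.oriented[probe_start:probe_start + cfg.di_probe_len]
        if len(probe) < cfg.di_probe_len:
            continue
        region = roi.oriented[probe_start + cfg.di_probe_len + 3:
                              min(probe_start + cfg.di_search_bp, roi.orf_start_o)]
        duplex = best_antiparallel_duplex(probe, region)
        if duplex is None or duplex[1] < cfg.min_di_pairs:
            continue
        scored.append((mm, duplex[1], p))
    if not scored:
        return None
    scored.sort(key=lambda t: (t[0], -t[1], t[2]))
    mm, pairs, p = scored[0]
    return FivePrimeResult(five_o=p, mismatches=mm, di_pairs=pairs,
                           candidates=scored)


def find_div_basal_stem(roi: Roi, dv_start_o: int,
                        cfg: IntronConfig | None = None
                        ) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """DIV basal stem: antiparallel WC complement (<= 1 mismatch over the
    probe) of the k-mer immediately 5' of DV, inside the ORF or within the
    200 bp upstream of the ORF start.  Returns ROI-local (probe, partner)
    intervals; more pairs win, then leftmost."""
    cfg = cfg or IntronConfig()
    k = cfg.basal_probe_len
    if dv_start_o - k < 0:
        return None
    probe = roi.oriented[dv_start_o - k:dv_start_o]
    lo = max(0, roi.orf_start_o - cfg.basal_upstream_bp)
    region = roi.oriented[lo:roi.orf_end_o]
    best: tuple[int, int] | None = None
    for off in range(len(region) - k + 1):
        w = region[off:off + k]
        pairs = sum(can_pair(probe[i], w[k - 1 - i], allow_gu=False) for i in range(k))
        if pairs >= max(6, k - 1):
            if best is None or pairs > best[1]:
                best = (off, pairs)
    if best is None:
        return None
    off = best[0]
    return ((dv_start_o - k, dv_start_o), (lo + off, lo + off + k))


def _find_ebs(probe: str, region: str, region_offset: int,
              max_mismatch: int) -> tuple[int, int, int] | None:
    """Best antiparallel WC complement of an IBS probe; (start, end, mismatches)."""
    hit = best_antiparallel_duplex(probe, region)
    if hit is None:
        return None
    off, pairs = hit
    mism = len(probe) - pairs
    if mism > max_mismatch:
        return None
    return region_offset + off, region_offset + off + len(probe), mism


def map_ebs_ibs(roi: Roi, five_o: int, three_o: int,
                intron_class: str, cfg: IntronConfig | None = None) -> TargetSiteReport:
    """EBS-IBS target pairing.

    IBS1 is the last 6 nt of the 5' exon (3-4 nt for group IIC, where no
    IBS2-EBS2 interaction is reported); EBS windows are searched in the DI
    region as antiparallel WC complements with a small mismatch budget.
    EBS3 is, by package convention, the base immediately 3' of EBS1.
    """
    cfg = cfg or IntronConfig()
    iic = intron_class == "IIC"
    ibs1_len = 4 if iic else 6
    if five_o < ibs1_len + (0 if iic else 6):
        return TargetSiteReport(computable=False)
    ibs1 = roi.oriented[five_o - ibs1_len:five_o]
    region_start = five_o + len(FIVE_PRIME_CONSENSUS)
    region_end = min(five_o + cfg.ebs_search_bp, roi.orf_start_o)
    region = roi.oriented[region_start:region_end]

    report = TargetSiteReport(computable=True, ibs1=ibs1, ibs1_len=ibs1_len)
    e1 = _find_ebs(ibs1, region, region_start, cfg.ebs_max_mismatch)
    if e1:
        s, e, mm = e1
        report.ebs1 = roi.to_top(s, e)
        report.ibs1_mismatches = mm
        # EBS3 convention: the base immediately 3' of EBS1 in DI
        if e < len(roi.oriented) and three_o < len(roi.oriented):
            report.ebs3 = roi.to_top(e, e + 1)
            report.ebs3_match = can_pair(roi.oriented[e], roi.oriented[three_o],
                                         allow_gu=False)
    if not iic:
        ibs2 = roi.oriented[five_o - ibs1_len - 6:five_o - ibs1_len]
        report.ibs2 = ibs2
        e2 = _find_ebs(ibs2, region, region_start, cfg.ebs_max_mismatch)
        if e2:
            s, e, mm = e2
            report.ebs2 = roi.to_top(s, e)
            report.ibs2_mismatches = mm
    # upstream stem-loop of the 5' exon (attC bs stands in for it in IIC-attC)
    up = roi.oriented[max(0, five_o - 100):five_o]
    ups = find_stem_loops(up, min_stem=5) if len(up) >= 15 else []
    if ups:
        report.upstream_hairpin = ups[0]
    return report


def check_iic_attc_context(model: IntronModel, attc_sites,
                           cassette_strand: str | None,
                           seq: GenomicSequence | str,
                           adjacency_bp: int = 50) -> ContextFlags:
    """Insertion-context flags for the IIC-attC lifestyle: junction at the
    TTGT/T consensus, placement within/immediately after an attC bottom
    strand, and orientation opposite to cassette transcription."""
    flags = ContextFlags()
    res = residues_of(seq)
    if model.five_prime is None and model.three_prime is None:
        return flags
    # the insertion junction on the top strand: the 5'-exon edge
    if model.strand == "+":
        junction = model.five_prime if model.five_prime is not None else model.three_prime
    else:
        junction = model.five_prime if model.five_prime is not None else model.three_prime
    for site in attc_sites:
        iv = site.interval
        if iv.contains(junction):
            flags.inside_attc_bs = True
            flags.attc_adjacent = True
            break
        dist = max(iv.start - junction, junction - iv.end, 0)
        if dist <= adjacency_bp:
            flags.attc_adjacent = True
        if dist <= 5:
            flags.inside_attc_bs = True
    if model.five_prime is not None and model.three_prime is not None:
        if model.strand == "+":
            exon5 = res[max(0, model.five_prime - 4):model.five_prime]
            exon3_first = res[model.three_prime] if model.three_prime < len(res) else ""
        else:
            exon5 = revcomp(res[model.five_prime:model.five_prime + 4])
            exon3_first = revcomp(res[model.three_prime - 1]) if model.three_prime >= 1 else ""
        flags.ttgtt_junction = exon5 == "TTGT" and exon3_first == "T"
    if cassette_strand in ("+", "-"):
        flags.orientation_opposite = model.strand != cassette_strand
    return flags


def call_integrity(model: IntronModel, iep_hit: IEPHit) -> str:
    """full <=> both boundaries resolved, RT0-7 and X present, no frame
    disruptions; 5'-truncated <=> 3' resolved but 5' unresolved; else
    fragmented."""
    domains_ok = all(iep_hit.domain_status(d) == "present" for d in RT_CORE + ("X",))
    if (model.five_prime is not None and model.three_prime is not None
            and domains_ok and iep_hit.frame_disruptions == 0):
        return "full"
    if model.three_prime is not None and model.five_prime is None:
        return "five_prime_truncated"
    return "fragmented"


def excised_sequences(seq: GenomicSequence | str, model: IntronModel,
                      exon_bp: int = 30) -> dict[str, str]:
    """Excised intron plus flanking exon windows, on the intron's coding
    orientation (keys: intron, exon5, exon3).  Unresolved boundaries yield
    an empty dict."""
    if model.interval is None:
        return {}
    res = residues_of(seq)
    lo, hi = model.interval.start, model.interval.end
    intron = res[lo:hi]
    exon5 = res[max(0, lo - exon_bp):lo]
    exon3 = res[hi:hi + exon_bp]
    if model.strand == "-":
        intron, exon5, exon3 = revcomp(intron), revcomp(exon3), revcomp(exon5)
    return {"intron": intron, "exon5": exon5, "exon3": exon3}


def annotate_intron(seq: GenomicSequence | str, iep_hit: IEPHit,
                    iep_refs: list[PanelEntry],
                    cfg: IntronConfig | None = None,
                    attc_sites=None, cassette_strand: str | None = None,
                    seq_id: str | None = None) -> IntronModel:
    """Full per-IEP annotation: classification, 3' then 5' boundary, DIV
    basal stem, EBS-IBS report, context flags and integrity call."""
    cfg = cfg or IntronConfig()
    iep_class, _ = classify_intron(iep_hit, iep_refs, margin=cfg.class_margin)
    ribo_class = RIBOZYME_CLASS.get(iep_class, "unclassified")
    roi = Roi(seq, iep_hit.interval, cfg, seq_id=seq_id)
    model = IntronModel(seq_id=roi.seq_id, strand=roi.strand, five_prime=None,
                        three_prime=None, interval=None,
                        iep_class=iep_class, intron_class=ribo_class)

    three = find_three_prime_end(roi, cfg, intron_class=ribo_class)
    if three is not None:
        dv_lo = roi.orf_end_o + three.dv.start
        dv_hi = roi.orf_end_o + three.dv.end
        dvi_lo = roi.orf_end_o + three.dvi.start
        dvi_hi = roi.orf_end_o + three.dvi.end
        model.dv = three.dv
        model.dvi = three.dvi
        model.dv_interval = roi.to_top(dv_lo, dv_hi)
        model.dvi_interval = roi.to_top(dvi_lo, dvi_hi)
        model.dv_triad = three.triad
        model.dv_ay_bulge = three.ay_bulge
        if three.dvi_bulged_a is not None:
            model.dvi_bulged_a = roi.pos_to_top(three.dvi_bulged_a)
        if three.tier == 1:
            model.deviations.append("three_prime_relaxed_to_AY")
        elif three.tier == 2:
            model.deviations.append("three_prime_unmatched")
        three_edge_top = roi.pos_to_top(three.three_o)
        model.three_prime = three_edge_top

        five = find_five_prime_end(roi, cfg)
        if five is not None:
            model.five_prime = roi.pos_to_top(five.five_o)
            if five.mismatches > 0:
                model.deviations.append("five_prime_consensus_deviant")
            basal = find_div_basal_stem(roi, dv_lo, cfg)
            if basal is not None:
                (p0, p1), (q0, q1) = basal
                model.div_basal_stem = (roi.to_top(p0, p1), roi.to_top(q0, q1))
            target = map_ebs_ibs(roi, five.five_o, three.three_o, ribo_class, cfg)
            model.target = target
            if target.ebs1 is not None:
                model.ebs["EBS1"] = target.ebs1
            if target.ebs2 is not None:
                model.ebs["EBS2"] = target.ebs2
            if target.ebs3 is not None:
                model.ebs["EBS3"] = target.ebs3
            lo = min(model.five_prime, model.three_prime)
            hi = max(model.five_prime, model.three_prime)
            model.interval = Interval(roi.seq_id, lo, hi, roi.strand)

    model.integrity = call_integrity(model, iep_hit)
    if attc_sites is not None:
        model.context = check_iic_attc_context(model, attc_sites,
                                               cassette_strand, seq)
    return model
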