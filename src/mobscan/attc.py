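"""attC site detection, clustering into integron loci / CALINs, and gene
cassette delineation.

An attC site is modeled from its two conserved boxes — R'' (consensus
5'-RYYYACC-3') and R' (5'-GTTRRRY-3') in that order on the site's coding
orientation — plus the structural requirement that the bottom strand folds
into a recombinogenic hairpin: R''.R' pairing (the R box) and an internal
pair of mutually complementary windows (the L box, which has no printed
sequence consensus).  Both strands are scanned; a cluster of >= 2 sites
within the inter-site distance threshold is an integron locus, classified
as a complete integron when an intI-like ORF lies within a window of the
array and as a CALIN otherwise.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

from . import align as _align
from .errors import ConfigurationError, InputError
from .panels import PanelEntry
from .rna_structure import nussinov_fold, pair_fraction
from .seq_core import GenomicSequence, Interval, ORFRecord, iupac_scan, residues_of, revcomp

logger = logging.getLogger(__name__)


@dataclass
class AttCConfig:
    """Tunable parameters of the consensus+structure attC model."""

    r2_pattern: str = "RYYYACC"      # R'' box on the coding orientation
    r1_pattern: str = "GTTRRRY"      # R' box
    box_mismatch: int = 0            # per-box mismatch budget
    site_length_range: tuple[int, int] = (40, 150)
    min_r_pairing: float = 6 / 7     # R''.R' antiparallel pairing fraction
    l_box_len: int = 10
    min_l_pairing: float = 1.0       # L''.L' pairing fraction
    l_loop_range: tuple[int, int] = (3, 30)
    max_arm_asym: int = 5            # |5' arm - 3' arm| length tolerance
    min_box_gap: int = 2             # min spacer between R'' / L'' and L' / R'


@dataclass
class AttCSite:
    """One detected attC site (all Intervals in top-strand coordinates).

    ``strand`` is the site's coding orientation (cassette direction);
    ``bs_strand`` is the strand whose bottom strand folds — the opposite.
    Box order along the coding orientation is R'' < L'' < L' < R'.
    """

    interval: Interval
    strand: str
    box_r2: Interval
    box_l2: Interval
    box_l1: Interval
    box_r1: Interval
    r_pairing: float
    l_pairing: float
    fold_score: int
    score: float

    @property
    def bs_strand(self) -> str:
        return "-" if self.strand == "+" else "+"


@dataclass
class GeneCassette:
    """Inter-attC segment (or the leader before the first site)."""

    interval: Interval
    upstream_attc: int | None       # index into locus.sites, None for leader
    downstream_attc: int | None
    orfs: list[ORFRecord] = field(default_factory=list)
    annotations: dict[int, str] = field(default_factory=dict)  # ORF idx -> label
    boundary_spanning: list[int] = field(default_factory=list)


@dataclass
class IntegronLocus:
    """A cluster of >= 2 attC sites, complete integron or CALIN."""

    seq_id: str
    sites: list[AttCSite]
    cassettes: list[GeneCassette] = field(default_factory=list)
    classification: str | None = None     # "complete_integron" | "CALIN"
    intI_hit: tuple[Interval, float] | None = None

    @property
    def interval(self) -> Interval:
        return Interval(self.seq_id, self.sites[0].interval.start,
                        self.sites[-1].interval.end)


def _best_l_box(interior: str, cfg: AttCConfig) -> tuple[float, int, int] | None:
    """Best mutually pairing (L'', L') window pair inside the interior.

    Returns (pairing_fraction, l2_start, l1_start) in interior-local
    coordinates, constrained by central loop length and arm symmetry.
    """
    n = len(interior)
    l = cfg.l_box_len
    lo, hi = cfg.l_loop_range
    best = None
    for w1 in range(cfg.min_box_gap, n - 2 * l - lo + 1):
        for loop in range(lo, hi + 1):
            w2 = w1 + l + loop
            if w2 + l > n - cfg.min_box_gap:
                break
            if abs(w1 - (n - (w2 + l))) > cfg.max_arm_asym:
                continue
            frac = pair_fraction(interior[w1:w1 + l], interior[w2:w2 + l])
            if best is None or frac > best[0] or (frac == best[0] and (w1, w2) < best[1:]):
                best = (frac, w1, w2)
    return best


def scan_attc(seq: GenomicSequence | str, config: AttCConfig | None = None,
              seq_id: str | None = None) -> list[AttCSite]:
    """Detect attC sites on both strands; overlaps resolved by score then
    leftmost.  Returns an empty list when nothing qualifies."""
    cfg = config or AttCConfig()
    res = residues_of(seq)
    sid = seq_id or (seq.id if isinstance(seq, GenomicSequence) else "seq")
    L = len(res)
    lmin, lmax = cfg.site_length_range
    blen_r2, blen_r1 = len(cfg.r2_pattern), len(cfg.r1_pattern)

    candidates: list[AttCSite] = []
    for orient in ("+", "-"):
        s = res if orient == "+" else revcomp(res)
        r2_hits = [p for p, st, _ in iupac_scan(cfg.r2_pattern, s, cfg.box_mismatch, strands="+")]
        r1_hits = [p for p, st, _ in iupac_scan(cfg.r1_pattern, s, cfg.box_mismatch, strands="+")]
        if not r2_hits or not r1_hits:
            continue
        r1_hits.sort()
        for a in r2_hits:
            lo_i = bisect.bisect_left(r1_hits, a + blen_r2)
            for b in r1_hits[lo_i:]:
                span = b + blen_r1 - a
                if span < lmin:
                    continue
                if span > lmax:
                    break
                r_frac = pair_fraction(s[a:a + blen_r2], s[b:b + blen_r1])
                if r_frac < cfg.min_r_pairing:
                    continue
                interior = s[a + blen_r2:b]
                lbox = _best_l_box(interior, cfg)
                if lbox is None or lbox[0] < cfg.min_l_pairing:
                    continue
                l_frac, w1, w2 = lbox
                fold = nussinov_fold(revcomp(s[a:b + blen_r1])).max_pairs
                # local (oriented) box intervals
                boxes_local = {
                    "r2": (a, a + blen_r2),
                    "l2": (a + blen_r2 + w1, a + blen_r2 + w1 + cfg.l_box_len),
                    "l1": (a + blen_r2 + w2, a + blen_r2 + w2 + cfg.l_box_len),
                    "r1": (b, b + blen_r1),
                }
                if orient == "+":
                    def to_top(x, y):
                        return Interval(sid, x, y, "+")
                else:
                    def to_top(x, y):
                        return Interval(sid, L - y, L - x, "-")
                site_iv = to_top(a, b + blen_r1)
                candidates.append(AttCSite(
                    interval=Interval(sid, site_iv.start, site_iv.end),
                    strand=orient,
                    box_r2=to_top(*boxes_local["r2"]),
                    box_l2=to_top(*boxes_local["l2"]),
                    box_l1=to_top(*boxes_local["l1"]),
                    box_r1=to_top(*boxes_local["r1"]),
                    r_pairing=r_frac, l_pairing=l_frac, fold_score=fold,
                    score=r_frac * blen_r2 + l_frac * cfg.l_box_len,
                ))

    candidates.sort(key=lambda c: (-c.score, c.interval.start))
    kept: list[AttCSite] = []
    for c in candidates:
        if all(not c.interval.overlaps(k.interval) for k in kept):
            kept.append(c)
    kept.sort(key=lambda c: c.interval.start)
    return kept


def cluster_attc(sites: list[AttCSite], threshold_bp: int = 8000) -> list[IntegronLocus]:
    """Single-linkage chaining of attC sites into loci.

    Successive sites whose inter-site gap (next start minus previous end) is
    <= ``threshold_bp`` join one locus; loci with < 2 sites are discarded.
    """
    if not sites:
        return []
    seq_ids = {s.interval.seq_id for s in sites}
    if len(seq_ids) > 1:
        raise InputError(f"cluster_attc: mixed sequence ids {sorted(seq_ids)}")
    seq_id = seq_ids.pop()
    ordered = sorted(sites, key=lambda s: s.interval.start)
    loci: list[list[AttCSite]] = [[ordered[0]]]
    for site in ordered[1:]:
        if site.interval.start - loci[-1][-1].interval.end <= threshold_bp:
            loci[-1].append(site)
        else:
            loci.append([site])
    return [IntegronLocus(seq_id=seq_id, sites=group)
            for group in loci if len(group) >= 2]


def delineate_cassettes(locus: IntegronLocus, orfs: list[ORFRecord],
                        leader_bp: int = 2000) -> IntegronLocus:
    """Attach gene cassettes: the leader segment before the first site plus
    one cassette per inter-site segment; ORFs assigned by midpoint."""
    cassettes: list[GeneCassette] = []
    first = locus.sites[0].interval
    leader_start = max(0, first.start - leader_bp)
    if leader_start < first.start:
        cassettes.append(GeneCassette(
            interval=Interval(locus.seq_id, leader_start, first.start),
            upstream_attc=None, downstream_attc=0))
    for k in range(len(locus.sites) - 1):
        a, b = locus.sites[k].interval.end, locus.sites[k + 1].interval.start
        if a < b:
            cassettes.append(GeneCassette(
                interval=Interval(locus.seq_id, a, b),
                upstream_attc=k, downstream_attc=k + 1))
    for cass in cassettes:
        for orf in orfs:
            if cass.interval.contains(orf.interval.midpoint):
                cass.orfs.append(orf)
                inside = (orf.interval.start >= cass.interval.start
                          and orf.interval.end <= cass.interval.end)
                if not inside:
                    cass.boundary_spanning.append(len(cass.orfs) - 1)
    locus.cassettes = cassettes
    return locus


def classify_locus(
    seq: GenomicSequence | str,
    locus: IntegronLocus,
    inti_refs: list[PanelEntry],
    orfs: list[ORFRecord],
    window_bp: int = 10000,
    min_identity: float = 35.0,
    min_coverage: float = 0.7,
) -> IntegronLocus:
    """Complete integron when an ORF within ``window_bp`` of the array aligns
    to an intI reference above identity/coverage thresholds; else CALIN."""
    if not inti_refs:
        raise ConfigurationError("intI reference panel is empty")
    span = locus.interval
    lo, hi = span.start - window_bp, span.end + window_bp
    ref_kmers = [(ref, _align.kmer_set(ref.protein)) for ref in inti_refs]
    best: tuple[Interval, float] | None = None
    for orf in orfs:
        if not (lo <= orf.interval.midpoint < hi) or len(orf.protein) < 50:
            continue
        q_kmers = _align.kmer_set(orf.protein)
        for ref, rk in ref_kmers:
            if not _align.shares_kmers(q_kmers, rk):
                continue
            stats = _align.align_stats(orf.protein, ref.protein, mode="local")
            if (stats and stats.identity >= min_identity
                    and stats.ref_coverage >= min_coverage):
                if best is None or stats.identity > best[1]:
                    best = (orf.interval, stats.identity)
    locus.intI_hit = best
    locus.classification = "complete_integron" if best else "CALIN"
    return locus
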