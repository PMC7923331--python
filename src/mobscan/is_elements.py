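"""IS200/605-superfamily element detection.

Elements are called from tnpA (HUH transposase) / tnpB homology against a
labeled panel, grouped when close, and bounded by the best subterminal
palindromic hairpin within a window of the outermost ORF ends — the family
has no terminal inverted repeats; hairpin ends are its hallmark.  The
tnpA/tnpB opposite-orientation configuration is characteristic of the
IS605 group.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import align as _align
from .errors import ConfigurationError
from .panels import PanelEntry
from .rna_structure import Hairpin, find_stem_loops
from .seq_core import GenomicSequence, Interval, ORFRecord, find_orfs, residues_of


@dataclass
class GeneHit:
    orf: ORFRecord
    ref: PanelEntry
    identity: float
    similarity: float


@dataclass
class ISElement:
    """One IS200/605-like element."""

    seq_id: str
    interval: Interval
    tnpA: GeneHit | None
    tnpB: GeneHit | None
    configuration: str          # opposite_orientation|same_orientation|tnpA_only|tnpB_only
    left_end: Hairpin | None    # coordinates are top-strand (shifted)
    right_end: Hairpin | None
    group_call: str             # IS605_group|IS200_like|partial|unclassified
    sequence: str = ""


@dataclass
class ISConfig:
    min_identity: float = 35.0
    pair_distance: int = 2000
    end_window_bp: int = 150
    hairpin_min_stem: int = 6
    hairpin_loop_range: tuple[int, int] = (3, 12)


def _gene_hits(orfs: list[ORFRecord], refs: list[PanelEntry],
               cfg: ISConfig) -> dict[str, list[GeneHit]]:
    by_role: dict[str, list[GeneHit]] = {"tnpA": [], "tnpB": []}
    ref_kmers = [(r, _align.kmer_set(r.protein)) for r in refs]
    for orf in orfs:
        if len(orf.protein) < 50:
            continue
        qk = _align.kmer_set(orf.protein)
        best: GeneHit | None = None
        for ref, rk in ref_kmers:
            if ref.role not in by_role or not _align.shares_kmers(qk, rk):
                continue
            stats = _align.align_stats(orf.protein, ref.protein, mode="local")
            if stats is None or stats.identity < cfg.min_identity:
                continue
            if stats.ref_coverage < 0.5:
                continue
            if best is None or stats.identity > best.identity:
                best = GeneHit(orf=orf, ref=ref, identity=stats.identity,
                               similarity=stats.similarity)
        if best:
            by_role[best.ref.role].append(best)
    return by_role


def _best_end_hairpin(res: str, lo: int, hi: int, cfg: ISConfig) -> Hairpin | None:
    lo, hi = max(0, lo), min(len(res), hi)
    if hi - lo < 2 * cfg.hairpin_min_stem + cfg.hairpin_loop_range[0]:
        return None
    hps = find_stem_loops(res[lo:hi], min_stem=cfg.hairpin_min_stem,
                          loop_range=cfg.hairpin_loop_range, allow_gu=False)
    return hps[0].shifted(lo) if hps else None


def find_is_elements(seq: GenomicSequence | str, tnp_refs: list[PanelEntry],
                     config: ISConfig | None = None,
                     orfs: list[ORFRecord] | None = None,
                     seq_id: str | None = None) -> list[ISElement]:
    """Detect IS200/605-like elements; empty panel raises ConfigurationError."""
    cfg = config or ISConfig()
    if not tnp_refs:
        raise ConfigurationError("tnpA/tnpB reference panel is empty")
    res = residues_of(seq)
    sid = seq_id or (seq.id if isinstance(seq, GenomicSequence) else "seq")
    if orfs is None:
        orfs = find_orfs(res, seq_id=sid)
    hits = _gene_hits(orfs, tnp_refs, cfg)

    used_b: set[int] = set()
    elements: list[ISElement] = []
    for a in sorted(hits["tnpA"], key=lambda h: h.orf.interval.start):
        partner = None
        for idx, b in enumerate(hits["tnpB"]):
            if idx in used_b:
                continue
            gap = max(b.orf.interval.start - a.orf.interval.end,
                      a.orf.interval.start - b.orf.interval.end, 0)
            if gap <= cfg.pair_distance:
                partner = (idx, b)
                break
        if partner:
            used_b.add(partner[0])
            elements.append(_build_element(res, sid, a, partner[1], cfg))
        else:
            elements.append(_build_element(res, sid, a, None, cfg))
    for idx, b in enumerate(hits["tnpB"]):
        if idx not in used_b:
            elements.append(_build_element(res, sid, None, b, cfg))
    elements.sort(key=lambda e: e.interval.start)
    return elements


def _build_element(res: str, sid: str, a: GeneHit | None, b: GeneHit | None,
                   cfg: ISConfig) -> ISElement:
    parts = [h for h in (a, b) if h]
    lo = min(h.orf.interval.start for h in parts)
    hi = max(h.orf.interval.end for h in parts)
    left = _best_end_hairpin(res, lo - cfg.end_window_bp, lo + 10, cfg)
    right = _best_end_hairpin(res, hi - 10, hi + cfg.end_window_bp, cfg)
    start = left.start if left else lo
    end = right.end if right else hi

    if a and b:
        configuration = ("opposite_orientation"
                         if a.orf.strand != b.orf.strand else "same_orientation")
    elif a:
        configuration = "tnpA_only"
    else:
        configuration = "tnpB_only"

    if a and b and configuration == "opposite_orientation" and left and right:
        group = "IS605_group"
    elif a and not b and bool(left) != bool(right):
        group = "IS200_like"   # single-ended tnpA-only candidate
    elif not (a and b and left and right):
        group = "partial"
    else:
        group = "unclassified"

    return ISElement(seq_id=sid, interval=Interval(sid, start, end),
                     tnpA=a, tnpB=b, configuration=configuration,
                     left_end=left, right_end=right, group_call=group,
                     sequence=res[start:end])


@dataclass
class ElementComparison:
    nucleotide_identity: float
    left_end: dict | None
    right_end: dict | None


def _compare_ends(x: Hairpin | None, y: Hairpin | None,
                  sx: str, sy: str, off_x: int, off_y: int) -> dict | None:
    if x is None or y is None:
        return None
    arm_x = "".join(sx[i - off_x] for i, _ in x.pair_list)
    arm_y = "".join(sy[i - off_y] for i, _ in y.pair_list)
    n = min(len(arm_x), len(arm_y))
    ident = sum(arm_x[i] == arm_y[i] for i in range(n)) / max(len(arm_x), len(arm_y))
    return {
        "stem_len": (x.stem_pairs, y.stem_pairs),
        "loop_len": (x.loop_len, y.loop_len),
        "stem_identity": 100.0 * ident,
    }


def compare_elements(a: ISElement, b: ISElement) -> ElementComparison:
    """Global nucleotide identity of two element spans plus per-end
    stem/loop congruence."""
    stats = _align.align_stats(a.sequence, b.sequence, mode="global", protein=False)
    ident = stats.identity if stats else 0.0
    return ElementComparison(
        nucleotide_identity=ident,
        left_end=_compare_ends(a.left_end, b.left_end, a.sequence, b.sequence,
                               a.interval.start, b.interval.start),
        right_end=_compare_ends(a.right_end, b.right_end, a.sequence, b.sequence,
                                a.interval.start, b.interval.start),
    )
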