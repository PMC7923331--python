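"""Synthetic mobile-element landscapes with exact planted truth.

The generator emulates the genomic structures the pipeline targets: attC
arrays with consensus R''/R' boxes and mutually complementary L boxes on a
foldable bottom strand, cassette ORFs and toxin/antitoxin pairs, group
IIC-attC introns inserted at a TTGT/T junction in opposite orientation,
group IIB introns immediately downstream of an attC site with engineered
EBS1/EBS2/EBS3 complements, 5'-truncated introns, IS605-configuration
elements with subterminal hairpins, and intI genes — plus uniform point
mutations applied last.

Draw order is fixed (background, then plants in list order, then mutation)
so a config is byte-reproducible.  Planted anchors are guaranteed
unambiguous: after assembly the generator re-runs the local anchor
searches and regenerates the landscape with a salted seed whenever a
random background window ties or beats a planted anchor.  Planted hairpins
are flanked by non-pairing AA guards so detected stem extents equal the
planted extents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import attc as _attc
from . import introns as _introns
from . import is_elements as _ise
from .errors import PlacementError
from .gff import GFFFeature
from .panels import PanelEntry, ReferencePanels
from .seq_core import GenomicSequence, Interval, find_orfs, revcomp

# most-frequent E. coli K-12 codon per amino acid (deterministic back-translation)
BACK_TABLE = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGC",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCG", "Q": "CAG", "R": "CGC", "S": "AGC", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAT",
}

_WCC = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _wc(s: str) -> str:
    return "".join(_WCC[c] for c in s)


def _rc(s: str) -> str:
    return _wc(s)[::-1]


def back_translate(protein: str) -> str:
    return "".join(BACK_TABLE[a] for a in protein)


def _rand_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p)) if n else ""


def _rand_from(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


def mutate(seq: str, rate: float, seed_or_rng) -> str:
    """Independent per-site substitution (always to a different base)."""
    if not (0 <= rate <= 1):
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0 or not seq:
        return seq
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    idx = {ord(b): i for i, b in enumerate("ACGT")}
    codes = np.array([idx.get(c, 0) for c in arr], dtype=np.int8)
    hit = rng.random(len(arr)) < rate
    shift = rng.integers(1, 4, size=len(arr))
    new_codes = (codes + shift) % 4
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr[hit] = lut[new_codes[hit]]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Config and truth containers
# ---------------------------------------------------------------------------

@dataclass
class PlantSpec:
    kind: str
    position: "int | str" = "auto"
    params: dict = field(default_factory=dict)


@dataclass
class GeneratorConfig:
    seed: int
    landscape_length: int = 100_000
    gc_content: float = 0.5
    plants: list[PlantSpec] = field(default_factory=list)
    mutation_rate: float = 0.0
    max_attempts: int = 25


@dataclass
class TruthFeature:
    kind: str
    start: int
    end: int
    strand: str
    label: str = ""
    anchors: dict = field(default_factory=dict)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class SyntheticTruth:
    seq_id: str
    landscape_length: int
    features: list[TruthFeature]
    config_seed: int
    seed_used: int
    mutation_rate: float

    def by_kind(self, kind: str) -> list[TruthFeature]:
        return [f for f in self.features if f.kind == kind]

    def to_json_dict(self) -> dict:
        return {
            "seq_id": self.seq_id,
            "landscape_length": self.landscape_length,
            "config_seed": self.config_seed,
            "seed_used": self.seed_used,
            "mutation_rate": self.mutation_rate,
            "features": [
                {"kind": f.kind, "start": f.start, "end": f.end,
                 "strand": f.strand, "label": f.label,
                 "anchors": {k: list(v) if isinstance(v, tuple) else v
                             for k, v in f.anchors.items()}}
                for f in self.features
            ],
        }

    def to_gff_features(self) -> list[GFFFeature]:
        out = []
        for i, f in enumerate(self.features):
            out.append(GFFFeature(seqid=self.seq_id, type=f.kind,
                                  start=f.start, end=f.end, strand=f.strand,
                                  source="mobscan-synthetic",
                                  attributes={"ID": f"truth{i}",
                                              "label": f.label or f.kind}))
        return out


# ---------------------------------------------------------------------------
# Block builder
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self) -> None:
        self.chunks: list[str] = []
        self.n = 0
        self.features: list[TruthFeature] = []

    def add(self, s: str) -> int:
        start = self.n
        self.chunks.append(s)
        self.n += len(s)
        return start

    def feature(self, kind: str, start: int, end: int, strand: str,
                label: str = "", **anchors) -> TruthFeature:
        f = TruthFeature(kind=kind, start=start, end=end, strand=strand,
                         label=label, anchors=anchors)
        self.features.append(f)
        return f

    def seq(self) -> str:
        return "".join(self.chunks)


def _orf_piece(b: _Builder, rng, protein: str, kind: str, label: str = "",
               strand: str = "+") -> tuple[int, int]:
    """Guarded ORF: an in-frame stop immediately before ATG pins the ORF's
    detected start to the planted start."""
    fwd = "TAA" + "ATG" + back_translate(protein) + "TAA"
    if strand == "+":
        p = b.add(fwd)
        span = (p + 3, p + len(fwd))
    else:
        p = b.add(_rc(fwd))
        span = (p, p + len(fwd) - 3)
    if kind:
        b.feature(kind, span[0], span[1], strand, label=label, orf=span)
    return span


# ---------------------------------------------------------------------------
# attC site
# ---------------------------------------------------------------------------

def _attc_boxes(rng) -> tuple[str, str]:
    """A concrete (R'', R') instance pair: R' from GTTRRRY, R'' derived so the
    antiparallel R-box pairing is 6/7 (position 6 of R'' stays unpaired)."""
    r1 = "GTT" + _rand_from(rng, "AG", 3) + _rand_from(rng, "CT", 1)
    r2 = _wc(r1[6]) + _wc(r1[5]) + _wc(r1[4]) + _wc(r1[3]) + "ACC"
    return r2, r1


def _place_attc_site(b: _Builder, rng) -> TruthFeature:
    r2, r1 = _attc_boxes(rng)
    # boundary bases must not pair, otherwise a shifted L-box window would
    # pair as perfectly as the planted one (translational ambiguity of a
    # complementary block)
    while True:
        sp1 = _rand_dna(rng, 5)
        sp2 = _rand_dna(rng, 5)
        if (sp1[4] != _wc(sp2[0])
                and sum(a == _wc(c) for a, c in zip(sp1, sp2[::-1])) <= 2):
            break
    l2 = _rand_dna(rng, 10)
    l1 = _rc(l2)
    while True:
        loop = _rand_dna(rng, 8)
        if loop[0] != _wc(loop[7]):
            break
    p = b.add(r2 + sp1 + l2 + loop + l1 + sp2 + r1)
    return b.feature(
        "attc_site", p, p + 52, "+",
        r2=(p, p + 7), l2=(p + 12, p + 22), l1=(p + 30, p + 40),
        r1=(p + 45, p + 52))


# ---------------------------------------------------------------------------
# intron construct (built in its own 5'->3' orientation)
# ---------------------------------------------------------------------------

def _bulged_arm(rng, prefix: str, arm_len: int) -> tuple[str, str]:
    """A hairpin 5' arm with a bulged A after position 4 (followed by a
    pyrimidine so the bulge reads A-then-Y); returns (bulged_arm, plain_arm)."""
    tail_len = arm_len - len(prefix)
    body = prefix + _rand_dna(rng, tail_len)
    arm = body[:4] + _rand_from(rng, "CGT", 1) + _rand_from(rng, "CT", 1) + body[6:arm_len]
    bulged = arm[:5] + "A" + arm[5:]
    return bulged, arm


def _intron_construct(rng, iep: PanelEntry, triad: str, ibs1: str, ibs3: str,
                      ibs2: str | None = None) -> tuple[str, dict, str]:
    """Returns (sequence, local oriented anchors, sequence) for one intron."""
    b = _Builder()
    b.add("GTGCG")                                   # five boundary at 0
    di_arm = _rand_dna(rng, 12)
    p = b.add(di_arm)
    anchors: dict = {"five": 0, "di_probe": (p, p + 12)}
    b.add(_rand_dna(rng, 8))
    if ibs2 is not None:
        p = b.add(_rc(ibs2))
        anchors["ebs2"] = (p, p + len(ibs2))
        b.add(_rand_dna(rng, 6))
    p = b.add(_rc(ibs1))
    anchors["ebs1"] = (p, p + len(ibs1))
    p = b.add(_wc(ibs3))
    anchors["ebs3"] = (p, p + 1)
    b.add(_rand_dna(rng, 10))
    p = b.add(_rc(di_arm))
    anchors["di_partner"] = (p, p + 12)
    b.add(_rand_dna(rng, 25))
    basal_probe = _rand_dna(rng, 6) + _rand_from(rng, "ACG", 2)
    p = b.add(_rc(basal_probe))
    anchors["basal_partner"] = (p, p + 8)
    b.add(_rand_dna(rng, 30))
    orf = _orf_piece(b, rng, iep.protein, kind="", strand="+")
    anchors["orf"] = orf
    b.add(_rand_dna(rng, 6))
    p = b.add(basal_probe)
    anchors["basal_probe"] = (p, p + 8)
    # DV: 12-pair stem with the catalytic triad at the arm base and an A.Y bulge
    dv_bulged, dv_arm = _bulged_arm(rng, triad, 12)
    loop = _rand_dna(rng, 4)
    p = b.add(dv_bulged + loop + _rc(dv_arm) + "AA")
    anchors["dv"] = (p, p + len(dv_bulged) + 4 + len(dv_arm))
    # DVI: 14-pair stem with a bulged A
    dvi_bulged, dvi_arm = _bulged_arm(rng, "", 14)
    loop2 = _rand_dna(rng, 4)
    p = b.add("AA" + dvi_bulged + loop2 + _rc(dvi_arm) + "AA")
    anchors["dvi"] = (p + 2, p + 2 + len(dvi_bulged) + 4 + len(dvi_arm))
    b.add("ATTTGAT")                                 # 3' consensus AXX(X)XRAY
    anchors["three"] = b.n
    return b.seq(), anchors, b.seq()


def _offset_anchors(anchors: dict, p: int) -> dict:
    return {k: ((v[0] + p, v[1] + p) if isinstance(v, tuple) else v + p)
            for k, v in anchors.items()}


def _flip_anchors(anchors: dict, p: int, n: int) -> dict:
    return {k: ((p + n - v[1], p + n - v[0]) if isinstance(v, tuple) else p + n - v)
            for k, v in anchors.items()}


def _place_iic_intron(b: _Builder, rng, panels: ReferencePanels) -> None:
    """IIC-attC intron: inserted on the bottom strand at a TTGT/T junction
    immediately 5' of the following attC site's R'' box (the attC bs end);
    the caller adds the site right after."""
    iep = next(e for e in panels.iep if e.label == "C")
    seq, anchors, _ = _intron_construct(rng, iep, triad="CGC",
                                        ibs1="TTGT", ibs3="T")
    b.add("A")                       # bottom strand: ...TTGT / T...
    p = b.add(_rc(seq))
    n = len(seq)
    g = _flip_anchors(anchors, p, n)
    b.features.append(TruthFeature(
        kind="iic_attc_intron", start=p, end=p + n, strand="-",
        label=iep.label, anchors=g))
    b.add("ACAA")                    # reads TTGT on the bottom strand


def _place_iib_intron(b: _Builder, rng, panels: ReferencePanels) -> None:
    """IIB intron immediately after an attC site, in cassette orientation,
    with engineered EBS1/EBS2/EBS3 complements."""
    iep = next(e for e in panels.iep if e.label == "CL1")
    b.add(_rand_dna(rng, 2))
    ibs2 = _rand_dna(rng, 6)
    while True:
        ibs1 = _rand_dna(rng, 6)
        if ibs1[-4:] != "TTGT":
            break
    ibs3 = "C"
    b.add(ibs2)
    b.add(ibs1)
    seq, anchors, _ = _intron_construct(rng, iep, triad="AGC",
                                        ibs1=ibs1, ibs3=ibs3, ibs2=ibs2)
    p = b.add(seq)
    g = _offset_anchors(anchors, p)
    b.features.append(TruthFeature(
        kind="iib_intron", start=p, end=p + len(seq), strand="+",
        label=iep.label, anchors=g))
    b.add(ibs3)
    b.add(_rand_dna(rng, 10))


def _place_truncated_intron(b: _Builder, rng, panels: ReferencePanels,
                            truncate_frac: float = 0.52) -> None:
    """5'-truncated intron: the 5' fraction (boundary, DI, and the IEP
    N-terminus through RT4) is deleted; only the 3' structures remain."""
    iep = next(e for e in panels.iep if e.label == "E")
    seq, anchors, _ = _intron_construct(rng, iep, triad="AGC",
                                        ibs1=_rand_dna(rng, 6), ibs3="C",
                                        ibs2=_rand_dna(rng, 6))
    orf_s, orf_e = anchors["orf"]
    cut = orf_s + int(truncate_frac * (orf_e - orf_s))
    kept = seq[cut:]
    p = b.add(kept)
    g = {}
    for k in ("orf", "basal_probe", "dv", "dvi", "three"):
        v = anchors[k]
        if isinstance(v, tuple):
            g[k] = (max(v[0], cut) - cut + p, v[1] - cut + p)
        else:
            g[k] = v - cut + p
    b.features.append(TruthFeature(
        kind="truncated_intron", start=p, end=p + len(kept), strand="+",
        label=iep.label, anchors=g))


# ---------------------------------------------------------------------------
# other plants
# ---------------------------------------------------------------------------

def _hairpin_piece(b: _Builder, rng, stem: int = 12, loop: int = 4) -> tuple[int, int]:
    arm = _rand_dna(rng, stem)
    p = b.add("AA" + arm + _rand_dna(rng, loop) + _rc(arm) + "AA")
    return (p + 2, p + 2 + 2 * stem + loop)


def _place_is_element(b: _Builder, rng, panels: ReferencePanels) -> None:
    tnpa = next(e for e in panels.tnp if e.role == "tnpA")
    tnpb = next(e for e in panels.tnp if e.role == "tnpB")
    left = _hairpin_piece(b, rng)
    b.add(_rand_dna(rng, 25))
    a_span = _orf_piece(b, rng, tnpa.protein, kind="", strand="-")
    b.add(_rand_dna(rng, 60))
    b_span = _orf_piece(b, rng, tnpb.protein, kind="", strand="+")
    b.add(_rand_dna(rng, 25))
    right = _hairpin_piece(b, rng)
    b.features.append(TruthFeature(
        kind="is605_element", start=left[0], end=right[1], strand="+",
        label="IS605_group",
        anchors={"tnpA": a_span, "tnpB": b_span,
                 "left_end": left, "right_end": right}))


def _place_ta_pair(b: _Builder, rng) -> None:
    toxin = _rand_from(rng, "ACDEFGHIKLMNPQRSTVWY", 70)
    anti = _rand_from(rng, "ACDEFGHIKLMNPQRSTVWY", 60)
    _orf_piece(b, rng, toxin, kind="ta_toxin", label="toxin")
    b.add(_rand_dna(rng, 4))
    _orf_piece(b, rng, anti, kind="ta_antitoxin", label="antitoxin")


def _place_cassette_orf(b: _Builder, rng) -> None:
    prot = _rand_from(rng, "ACDEFGHIKLMNPQRSTVWY", int(rng.integers(70, 121)))
    _orf_piece(b, rng, prot, kind="cassette_orf", label="cassette ORF")


def _build_attc_array(b: _Builder, rng, params: dict,
                      panels: ReferencePanels) -> None:
    n_sites = params.get("n_sites", 4)
    cassettes = params.get("cassettes", ["orf"] * max(0, n_sites - 1))
    iic_before = params.get("iic_before_site")
    iib_after = params.get("iib_after_site")
    is_downstream = params.get("is_downstream", False)
    if params.get("intI"):
        _orf_piece(b, rng, panels.inti[0].protein, kind="intI_gene", label="intI")
        b.add(_rand_dna(rng, 150))
    _place_cassette_orf(b, rng)      # leader cassette ORF
    b.add(_rand_dna(rng, 30))
    for k in range(n_sites):
        if iic_before == k:
            _place_iic_intron(b, rng, panels)
        _place_attc_site(b, rng)
        if iib_after == k:
            _place_iib_intron(b, rng, panels)
        if k < n_sites - 1:
            kind = cassettes[k] if k < len(cassettes) else "orf"
            b.add(_rand_dna(rng, 25))
            if kind == "orf":
                _place_cassette_orf(b, rng)
            elif kind == "ta":
                _place_ta_pair(b, rng)
            elif kind == "trunc":
                _place_truncated_intron(b, rng, panels)
            elif kind == "orf6":
                for _ in range(6):
                    _place_cassette_orf(b, rng)
                    b.add(_rand_dna(rng, 10))
            b.add(_rand_dna(rng, 25))
    if is_downstream:
        # an IS element directly downstream of the last attC in the array
        b.add(_rand_dna(rng, 100))
        _place_is_element(b, rng, panels)


def _build_plant(spec: PlantSpec, rng, panels: ReferencePanels) -> _Builder:
    b = _Builder()
    kind = spec.kind
    if kind == "attc_array":
        _build_attc_array(b, rng, spec.params, panels)
    elif kind == "is605_element":
        _place_is_element(b, rng, panels)
    elif kind == "intI_gene":
        _orf_piece(b, rng, panels.inti[0].protein, kind="intI_gene", label="intI")
    elif kind == "ta_operon_pair":
        _place_ta_pair(b, rng)
    elif kind == "iic_attc_intron":
        _place_iic_intron(b, rng, panels)
        _place_attc_site(b, rng)
    elif kind == "iib_intron":
        _place_attc_site(b, rng)
        _place_iib_intron(b, rng, panels)
    elif kind == "truncated_intron":
        _place_truncated_intron(b, rng, panels)
    else:
        raise PlacementError(f"unknown plant kind {kind!r}")
    return b


# ---------------------------------------------------------------------------
# landscape assembly + anchor verification
# ---------------------------------------------------------------------------

def default_landscape_config(seed: int, length: int = 100_000,
                             mutation_rate: float = 0.0) -> GeneratorConfig:
    """The standard study landscape: a complete integron array carrying a
    IIC-attC intron, a IIB intron and a TA cassette, plus a CALIN array with
    a truncated intron and an adjacent IS605 element."""
    plants = [
        PlantSpec(kind="attc_array", params=dict(
            n_sites=4, intI=True, cassettes=["orf", "ta", "orf"],
            iic_before_site=1, iib_after_site=2)),
        PlantSpec(kind="attc_array", params=dict(
            n_sites=3, intI=False, cassettes=["orf", "trunc"],
            is_downstream=True)),
    ]
    return GeneratorConfig(seed=seed, landscape_length=length, plants=plants,
                           mutation_rate=mutation_rate)


def small_landscape_config(seed: int, length: int = 30_000,
                           mutation_rate: float = 0.0) -> GeneratorConfig:
    """Compact landscape used for mutation-degradation sweeps."""
    plants = [
        PlantSpec(kind="attc_array", params=dict(
            n_sites=3, intI=True, cassettes=["orf", "orf"],
            iic_before_site=1, iib_after_site=1)),
        PlantSpec(kind="truncated_intron"),
        PlantSpec(kind="is605_element"),
    ]
    return GeneratorConfig(seed=seed, landscape_length=length, plants=plants,
                           mutation_rate=mutation_rate)


def _auto_positions(block_lens: list[int], L: int) -> list[int]:
    total = sum(block_lens)
    free = L - total
    if free < (len(block_lens) + 1) * 50:
        raise PlacementError("plants do not fit in the landscape")
    gap = free // (len(block_lens) + 1)
    positions = []
    cur = gap
    for n in block_lens:
        positions.append(cur)
        cur += n + gap
    return positions


def _find_matching_orf(seq_str: str, seq_id: str, f: TruthFeature) -> Interval | None:
    orf_s, orf_e = f.anchors["orf"]
    lo = max(0, f.start - 3600)
    hi = min(len(seq_str), f.end + 600)
    for orf in find_orfs(seq_str[lo:hi], min_len=150, seq_id=seq_id):
        s = orf.interval.start + lo
        e = orf.interval.end + lo
        if orf.strand != f.strand:
            continue
        if (f.strand == "+" and e == orf_e) or (f.strand == "-" and s == orf_s):
            return Interval(seq_id, s, e, f.strand)
    return None


def _verify_truth(seq_str: str, truth: SyntheticTruth,
                  panels: ReferencePanels) -> bool:
    """Re-run the local anchor searches; False when any planted anchor is
    ambiguous against its random context (triggers a salted regeneration)."""
    icfg = _introns.IntronConfig()
    iscfg = _ise.ISConfig()
    sid = truth.seq_id
    for f in truth.features:
        if f.kind in ("iic_attc_intron", "iib_intron", "truncated_intron"):
            hit_iv = _find_matching_orf(seq_str, sid, f)
            if hit_iv is None:
                return False
            roi = _introns.Roi(seq_str, hit_iv, icfg, seq_id=sid)
            ribo = "IIC" if f.kind == "iic_attc_intron" else "IIB"
            three = _introns.find_three_prime_end(roi, icfg, intron_class=ribo)
            if three is None:
                return False
            if roi.pos_to_top(three.three_o) != f.anchors["three"]:
                return False
            dv_iv = roi.to_top(roi.orf_end_o + three.dv.start,
                               roi.orf_end_o + three.dv.end)
            dvi_iv = roi.to_top(roi.orf_end_o + three.dvi.start,
                                roi.orf_end_o + three.dvi.end)
            if (dv_iv.start, dv_iv.end) != tuple(f.anchors["dv"]):
                return False
            if (dvi_iv.start, dvi_iv.end) != tuple(f.anchors["dvi"]):
                return False
            five = _introns.find_five_prime_end(roi, icfg)
            if f.kind == "truncated_intron":
                if five is not None:
                    return False
                continue
            if five is None:
                return False
            expected_five = f.anchors["five"]
            if roi.pos_to_top(five.five_o) != expected_five:
                return False
            basal = _introns.find_div_basal_stem(
                roi, roi.orf_end_o + three.dv.start, icfg)
            if basal is None:
                return False
            (_, _), (q0, q1) = basal
            part = roi.to_top(q0, q1)
            if (part.start, part.end) != tuple(f.anchors["basal_partner"]):
                return False
            if f.kind == "iib_intron":
                tgt = _introns.map_ebs_ibs(roi, five.five_o, three.three_o,
                                           "IIB", icfg)
                for name in ("ebs1", "ebs2"):
                    got = getattr(tgt, name)
                    if got is None or (got.start, got.end) != tuple(f.anchors[name]):
                        return False
                if tgt.ebs3_match is not True:
                    return False
        elif f.kind == "attc_site":
            lo = max(0, f.start - 120)
            hi = min(len(seq_str), f.end + 120)
            sites = _attc.scan_attc(seq_str[lo:hi], seq_id=sid)
            match = [s for s in sites
                     if (s.interval.start + lo, s.interval.end + lo) == (f.start, f.end)
                     and s.strand == f.strand]
            if len(match) != 1:
                return False
            s = match[0]
            for name, box in (("r2", s.box_r2), ("l2", s.box_l2),
                              ("l1", s.box_l1), ("r1", s.box_r1)):
                if (box.start + lo, box.end + lo) != tuple(f.anchors[name]):
                    return False
        elif f.kind == "is605_element":
            a_lo = min(f.anchors["tnpA"][0], f.anchors["tnpB"][0])
            b_hi = max(f.anchors["tnpA"][1], f.anchors["tnpB"][1])
            left = _ise._best_end_hairpin(seq_str, a_lo - iscfg.end_window_bp,
                                          a_lo + 10, iscfg)
            right = _ise._best_end_hairpin(seq_str, b_hi - 10,
                                           b_hi + iscfg.end_window_bp, iscfg)
            if left is None or (left.start, left.end) != tuple(f.anchors["left_end"]):
                return False
            if right is None or (right.start, right.end) != tuple(f.anchors["right_end"]):
                return False
    return True


def generate_landscape(config: GeneratorConfig,
                       panels: ReferencePanels | None = None
                       ) -> tuple[GenomicSequence, SyntheticTruth]:
    """Generate one landscape plus its planted-feature truth.

    Same config => identical output bytes.  Ambiguous-anchor landscapes are
    regenerated with a deterministic salted seed (bounded attempts).
    """
    panels = panels or ReferencePanels.default()
    L = config.landscape_length
    sid = f"synthetic_{config.seed}"
    for attempt in range(config.max_attempts):
        seed_used = config.seed + attempt * 1_000_003
        rng = np.random.default_rng(seed_used)
        background = _rand_dna(rng, L, config.gc_content)
        builders = [_build_plant(spec, rng, panels) for spec in config.plants]
        lens = [b.n for b in builders]
        if any(not isinstance(s.position, str) for s in config.plants):
            positions = []
            for spec, n in zip(config.plants, lens):
                if isinstance(spec.position, str):
                    raise PlacementError("mix of auto and explicit positions")
                positions.append(int(spec.position))
            order = sorted(range(len(positions)), key=lambda i: positions[i])
            prev_end = 0
            for i in order:
                if positions[i] < prev_end or positions[i] + lens[i] > L:
                    raise PlacementError(
                        f"plant {config.plants[i].kind} at {positions[i]} overlaps"
                        " a previous plant or exceeds the landscape")
                prev_end = positions[i] + lens[i]
        else:
            positions = _auto_positions(lens, L)

        arr = list(background)
        features: list[TruthFeature] = []
        for pos, b in zip(positions, builders):
            arr[pos:pos + b.n] = b.seq()
            for f in b.features:
                features.append(TruthFeature(
                    kind=f.kind, start=f.start + pos, end=f.end + pos,
                    strand=f.strand, label=f.label,
                    anchors=_offset_anchors(f.anchors, pos)))
        seq_str = "".join(arr)
        features.sort(key=lambda f: (f.start, f.end))
        truth = SyntheticTruth(seq_id=sid, landscape_length=L,
                               features=features, config_seed=config.seed,
                               seed_used=seed_used,
                               mutation_rate=config.mutation_rate)
        if not _verify_truth(seq_str, truth, panels):
            continue
        if config.mutation_rate > 0:
            mrng = np.random.default_rng(seed_used + 7919)
            seq_str = mutate(seq_str, config.mutation_rate, mrng)
        return GenomicSequence(id=sid, residues=seq_str), truth
    raise PlacementError(
        f"could not realize an unambiguous landscape for seed {config.seed} "
        f"in {config.max_attempts} attempts")


def write_truth(prefix, truth: SyntheticTruth) -> None:
    """Emit the truth ledger beside the FASTA: JSON with anchors + GFF3."""
    from .gff import write_gff3
    with open(f"{prefix}.truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    write_gff3(f"{prefix}.truth.gff3", truth.to_gff_features(),
               seq_lengths={truth.seq_id: truth.landscape_length})
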