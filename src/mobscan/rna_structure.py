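"""Minimal secondary-structure machinery.

Maximum base-pairing (Nussinov) folding and stem-loop scanning, used for the
attC bottom-strand hairpin, the intron DV/DVI helices and the subterminal
palindromic ends of IS200/605 elements.  The energy model is a pure pair
count — Watson-Crick plus (optionally) G.U wobble — with a 0.5 penalty per
bulged position; the pipeline uses structure qualitatively (presence and
shape of helices), not free energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AlphabetError, GeometryError

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}

BULGE_PENALTY = 0.5


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    """Watson-Crick (A.T/U, G.C) pairing, with G.U wobble when ``allow_gu``."""
    p = (a, b)
    return p in _WC or (allow_gu and p in _GU)


def _check_alphabet(window: str) -> str:
    w = window.upper().replace("U", "T")
    bad = set(w) - set("ACGT")
    if bad:
        raise AlphabetError(f"non-nucleotide characters in window: {sorted(bad)}")
    return w


@dataclass
class FoldResult:
    """Outcome of maximum-pairing folding of one window."""

    sequence: str
    dot_bracket: str
    max_pairs: int
    pairs: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class Hairpin:
    """A local stem-loop: ``[start, end)`` in window-local coordinates.

    ``pair_list`` holds (i, j) index pairs from outermost to innermost;
    ``score`` is ``stem_pairs - 0.5 * bulges``.
    """

    start: int
    end: int
    stem_pairs: int
    loop_len: int
    bulges: int
    pair_list: list[tuple[int, int]]
    score: float

    @property
    def apex(self) -> tuple[int, int]:
        i, j = self.pair_list[-1]
        return (i + 1, j)  # the enclosed loop interval

    def five_arm_positions(self) -> list[int]:
        return sorted(i for i, _ in self.pair_list)

    def shifted(self, offset: int) -> "Hairpin":
        return Hairpin(
            start=self.start + offset,
            end=self.end + offset,
            stem_pairs=self.stem_pairs,
            loop_len=self.loop_len,
            bulges=self.bulges,
            pair_list=[(i + offset, j + offset) for i, j in self.pair_list],
            score=self.score,
        )


def nussinov_fold(window: str, min_loop: int = 3, allow_gu: bool = True) -> FoldResult:
    """Maximum non-crossing base pairing by dynamic programming.

    Returns a structure achieving the maximum number of WC (+ G.U) pairs
    subject to a minimum hairpin loop of ``min_loop`` unpaired bases.
    The traceback is deterministic: at ties, j is left unpaired; otherwise
    j pairs with the smallest feasible k.
    """
    s = _check_alphabet(window)
    n = len(s)
    if min_loop < 0:
        raise ValueError("min_loop must be >= 0")
    if n == 0:
        return FoldResult(sequence=s, dot_bracket="", max_pairs=0)

    dp = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if can_pair(s[k], s[j], allow_gu):
                    left = dp[i][k - 1] if k > i else 0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + 1)
            dp[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if dp[i][j] == dp[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            if can_pair(s[k], s[j], allow_gu):
                left = dp[i][k - 1] if k > i else 0
                inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + inner + 1 == dp[i][j]:
                    pairs.append((k, j))
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break

    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    pairs.sort()
    return FoldResult(sequence=s, dot_bracket="".join(db), max_pairs=dp[0][n - 1],
                      pairs=pairs)


def _extend_hairpin(s: str, i: int, j: int, max_bulge: int, allow_gu: bool):
    """Extend a candidate stem outward from loop boundaries i (5') and j (3')."""
    pairs: list[tuple[int, int]] = []
    bulges = 0
    n = len(s)
    while i >= 0 and j < n:
        if can_pair(s[i], s[j], allow_gu):
            pairs.append((i, j))
            i -= 1
            j += 1
        elif bulges < max_bulge and i - 1 >= 0 and can_pair(s[i - 1], s[j], allow_gu):
            bulges += 1
            i -= 1
        elif bulges < max_bulge and j + 1 < n and can_pair(s[i], s[j + 1], allow_gu):
            bulges += 1
            j += 1
        else:
            break
    return pairs, bulges


def find_stem_loops(
    seq: str,
    min_stem: int = 5,
    loop_range: tuple[int, int] = (3, 12),
    max_bulge: int = 2,
    allow_gu: bool = True,
    suppress_overlaps: bool = True,
) -> list[Hairpin]:
    """All local hairpins with >= ``min_stem`` pairs and loop within range.

    With ``suppress_overlaps`` (default) overlapping candidates are
    suppressed greedily: hairpins are sorted by score descending then
    leftmost, and a hairpin is kept only if its span does not overlap an
    already-kept span.  Without it, every candidate is returned (callers
    that pair adjacent helices under extra constraints need the full set).
    """
    if min_stem < 4:
        raise ValueError("min_stem must be >= 4")
    s = _check_alphabet(seq)
    n = len(s)
    lo, hi = loop_range
    candidates: list[Hairpin] = []
    for loop_start in range(1, n):
        for loop_len in range(lo, hi + 1):
            j = loop_start + loop_len
            if j >= n:
                break
            pairs, bulges = _extend_hairpin(s, loop_start - 1, j, max_bulge, allow_gu)
            if len(pairs) >= min_stem:
                pairs_out = list(reversed(pairs))  # outermost first
                start = pairs_out[0][0]
                end = pairs_out[0][1] + 1
                candidates.append(Hairpin(
                    start=start, end=end, stem_pairs=len(pairs),
                    loop_len=loop_len, bulges=bulges, pair_list=pairs_out,
                    score=len(pairs) - BULGE_PENALTY * bulges,
                ))
    candidates.sort(key=lambda h: (-h.score, h.start, h.end))
    if not suppress_overlaps:
        return candidates
    kept: list[Hairpin] = []
    for h in candidates:
        if all(h.end <= k.start or k.end <= h.start for k in kept):
            kept.append(h)
    return kept


def pair_fraction(b1: str, b2: str, allow_gu: bool = False) -> float:
    """Fraction of positions pairing when b1 lies antiparallel against b2.

    Equal-length windows are compared position i against position n-1-i.
    Near-equal windows (length difference <= 2) slide the shorter against
    the longer and the best fraction (denominator: longer length) is
    returned.  A length difference > 2 raises :class:`GeometryError`.
    """
    a = _check_alphabet(b1)
    b = _check_alphabet(b2)
    if abs(len(a) - len(b)) > 2:
        raise GeometryError(
            f"window lengths differ by more than 2: {len(a)} vs {len(b)}"
        )
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    rev_long = long_[::-1]
    best = 0
    for off in range(len(long_) - len(short) + 1):
        hits = sum(
            can_pair(short[i], rev_long[off + i], allow_gu)
            for i in range(len(short))
        )
        best = max(best, hits)
    return best / len(long_)


# spec name: pair_boxes — box-against-box antiparallel pairing fraction
pair_boxes = pair_fraction


def best_antiparallel_duplex(
    probe: str,
    region: str,
    allow_gu: bool = False,
) -> tuple[int, int] | None:
    """Best antiparallel WC duplex of ``probe`` against windows of ``region``.

    Returns ``(region_start, n_pairs)`` of the best-pairing window of
    ``len(probe)``, ties broken leftmost; None when the region is shorter
    than the probe.
    """
    p = _check_alphabet(probe)
    r = _check_alphabet(region)
    m = len(p)
    if len(r) < m or m == 0:
        return None
    best_pos, best_pairs = 0, -1
    for off in range(len(r) - m + 1):
        w = r[off:off + m]
        hits = sum(can_pair(p[i], w[m - 1 - i], allow_gu) for i in range(m))
        if hits > best_pairs:
            best_pos, best_pairs = off, hits
    return best_pos, best_pairs
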