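"""Pairwise alignment helpers shared by the homology-based detectors.

Wraps Bio.Align.PairwiseAligner with blast-like conventions: identity is
exact matches over aligned columns (terminal gaps excluded), similarity is
the fraction of columns with a positive BLOSUM62 score.  A cheap shared
k-mer prefilter avoids aligning the many spurious background ORFs against
reference panels.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import InputError

BLOSUM62 = substitution_matrices.load("BLOSUM62")

_PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYBZX*"


def make_protein_aligner(mode: str = "local") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def make_dna_aligner(mode: str = "global") -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


@dataclass
class AlignmentStats:
    """Summary of one pairwise alignment (query vs reference)."""

    identity: float          # percent, matches / aligned columns
    similarity: float        # percent, positive-score columns / aligned columns
    aligned_columns: int
    query_start: int
    query_end: int
    ref_start: int
    ref_end: int
    ref_coverage: float      # aligned reference span / reference length
    score: float
    blocks: list[tuple[tuple[int, int], tuple[int, int]]]  # (q_block, r_block)

    def project_ref_interval(self, start: int, end: int) -> tuple[float, tuple[int, int] | None]:
        """Project a reference interval through the alignment.

        Returns (covered_fraction, query_interval_or_None) where the covered
        fraction counts reference positions inside aligned blocks.
        """
        covered = 0
        q_lo, q_hi = None, None
        for (qs, qe), (rs, re) in self.blocks:
            o_lo, o_hi = max(rs, start), min(re, end)
            if o_lo < o_hi:
                covered += o_hi - o_lo
                lo = qs + (o_lo - rs)
                hi = qs + (o_hi - rs)
                q_lo = lo if q_lo is None else min(q_lo, lo)
                q_hi = hi if q_hi is None else max(q_hi, hi)
        frac = covered / max(1, end - start)
        return frac, (None if q_lo is None else (q_lo, q_hi))


def _column_stats(q_aln: str, r_aln: str, protein: bool) -> tuple[int, int, int]:
    """(matches, positives, columns) over internal columns of an alignment."""
    # strip terminal gap columns
    lo, hi = 0, len(q_aln)
    while lo < hi and (q_aln[lo] == "-" or r_aln[lo] == "-"):
        lo += 1
    while hi > lo and (q_aln[hi - 1] == "-" or r_aln[hi - 1] == "-"):
        hi -= 1
    matches = positives = columns = 0
    for qc, rc in zip(q_aln[lo:hi], r_aln[lo:hi]):
        columns += 1
        if qc == "-" or rc == "-":
            continue
        if qc == rc:
            matches += 1
            positives += 1
        elif protein:
            try:
                if BLOSUM62[qc, rc] > 0:
                    positives += 1
            except KeyError:
                pass
    return matches, positives, columns


def align_stats(query: str, ref: str, mode: str = "local",
                protein: bool = True) -> AlignmentStats | None:
    """Align and summarize; None when no alignment scores above zero."""
    if not query or not ref:
        raise InputError("cannot align an empty sequence")
    aligner = make_protein_aligner(mode) if protein else make_dna_aligner(mode)
    try:
        aln = aligner.align(query, ref)[0]
    except (IndexError, ValueError):
        return None
    q_blocks, r_blocks = aln.aligned
    if len(q_blocks) == 0:
        return None
    q_aln, r_aln = str(aln[0]), str(aln[1])
    matches, positives, columns = _column_stats(q_aln, r_aln, protein)
    if columns == 0:
        return None
    blocks = [((int(qs), int(qe)), (int(rs), int(re)))
              for (qs, qe), (rs, re) in zip(q_blocks, r_blocks)]
    ref_lo, ref_hi = blocks[0][1][0], blocks[-1][1][1]
    return AlignmentStats(
        identity=100.0 * matches / columns,
        similarity=100.0 * positives / columns,
        aligned_columns=columns,
        query_start=blocks[0][0][0], query_end=blocks[-1][0][1],
        ref_start=ref_lo, ref_end=ref_hi,
        ref_coverage=(ref_hi - ref_lo) / len(ref),
        score=float(aln.score),
        blocks=blocks,
    )


def kmer_set(protein: str, k: int = 6) -> set[str]:
    return {protein[i:i + k] for i in range(len(protein) - k + 1)}


def shares_kmers(query_kmers: set[str], ref_kmers: set[str], min_shared: int = 2) -> bool:
    if len(query_kmers) > len(ref_kmers):
        query_kmers, ref_kmers = ref_kmers, query_kmers
    shared = 0
    for km in query_kmers:
        if km in ref_kmers:
            shared += 1
            if shared >= min_shared:
                return True
    return False
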