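"""Sequence substrate: FASTA I/O, coordinate conventions, degenerate-motif
scanning and naive ORF finding.

Conventions used throughout the package:

* coordinates are 0-based, half-open ``[start, end)`` on the top strand;
  GFF3 output converts to 1-based inclusive;
* DNA is canonical internally (U is normalized to T on input); RNA-facing
  display strings transliterate T back to U;
* the genetic code defaults to the bacterial table 11 with ATG/GTG/TTG
  accepted as starts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AlphabetError, CoordinateError, FastaFormatError

logger = logging.getLogger(__name__)

# IUPAC nucleotide degeneracy
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT_TABLE = str.maketrans(_COMPLEMENT)

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class GenomicSequence:
    """A nucleotide sequence (contig or genome) with linear/circular topology."""

    id: str
    residues: str
    topology: str = "linear"  # "linear" | "circular"

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - set(IUPAC_CODES)
        if bad:
            raise AlphabetError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise CoordinateError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.seq_id == other.seq_id and self.start < other.end and other.start < self.end


@dataclass
class ORFRecord:
    """A naively predicted open reading frame.

    ``interval`` is on the top strand; ``frame`` is the reading frame (0-2)
    on the coding strand.  ``has_start`` False implies the 5'-partial flag:
    the record covers a stop-bounded stretch lacking ATG/GTG/TTG.
    ``candidate_starts`` lists top-strand positions of every start codon in
    the stretch (no rule picks among alternative starts; all are reported).
    """

    interval: Interval
    frame: int
    has_start: bool
    has_stop: bool
    protein: str
    candidate_starts: list[int] = field(default_factory=list)

    @property
    def five_prime_partial(self) -> bool:
        return not self.has_start

    @property
    def three_prime_partial(self) -> bool:
        return not self.has_stop

    @property
    def strand(self) -> str:
        return self.interval.strand


def residues_of(seq: "GenomicSequence | str") -> str:
    return seq.residues if isinstance(seq, GenomicSequence) else seq


def read_fasta(path) -> list[GenomicSequence]:
    """Read a FASTA file into :class:`GenomicSequence` records.

    Order is preserved, residues are uppercased and U is normalized to T
    (with a logged note).  Malformed headers and empty files raise
    :class:`FastaFormatError` naming the offending line.
    """
    with open(path) as handle:
        lines = handle.read().splitlines()
    nonblank = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not nonblank:
        raise FastaFormatError(f"{path}: empty FASTA file")
    first_no, first = nonblank[0]
    if not first.startswith(">"):
        raise FastaFormatError(f"{path}:{first_no}: expected '>' header, got {first[:30]!r}")
    for no, ln in nonblank:
        if ln.startswith(">") and not ln[1:].strip():
            raise FastaFormatError(f"{path}:{no}: header line has no identifier")

    records: list[GenomicSequence] = []
    for rec in SeqIO.parse(path, "fasta"):
        res = str(rec.seq).upper()
        if "U" in res:
            logger.info("read_fasta: %s contains U; normalized to T", rec.id)
            res = res.replace("U", "T")
        records.append(GenomicSequence(id=rec.id, residues=res))
    return records


def write_fasta(path, seqs: list[GenomicSequence], width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


def revcomp(residues: str) -> str:
    """Reverse complement honoring IUPAC degeneracy (R<->Y, K<->M, ...)."""
    bad = set(residues.upper()) - set(IUPAC_CODES)
    if bad:
        raise AlphabetError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return residues.upper().translate(_COMPLEMENT_TABLE)[::-1]


def _match_matrix(pattern: str) -> list[np.ndarray]:
    """Per-pattern-column boolean lookup over ASCII codes: allowed[base]."""
    cols = []
    for p in pattern:
        allowed = np.zeros(128, dtype=bool)
        for b in IUPAC_CODES[p]:
            allowed[ord(b)] = True
        cols.append(allowed)
    return cols


def iupac_scan(
    pattern: str,
    seq: "GenomicSequence | str",
    max_mismatch: int = 0,
    strands: str = "+-",
    circular: bool = False,
) -> list[tuple[int, str, int]]:
    """Scan for a degenerate IUPAC ``pattern`` on one or both strands.

    Returns ``(position, strand, mismatches)`` tuples where ``position`` is
    the top-strand start of the matched window.  A degenerate pattern code
    matches any residue it denotes; degenerate residues in the subject match
    only if the pattern code covers them literally (subjects are expected to
    be concrete A/C/G/T in practice).  A pattern longer than the sequence
    yields an empty result.
    """
    pattern = pattern.upper().replace("U", "T")
    bad = set(pattern) - set(IUPAC_CODES)
    if bad:
        raise AlphabetError(f"non-IUPAC pattern characters: {sorted(bad)}")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    res = residues_of(seq)
    m = len(pattern)
    L = len(res)
    if m == 0 or L == 0 or (not circular and m > L):
        return []
    subject = res + (res[: m - 1] if circular and m > 1 else "")
    n_pos = len(subject) - m + 1
    if n_pos <= 0:
        return []
    codes = np.frombuffer(subject.encode("ascii"), dtype=np.uint8)

    hits: list[tuple[int, str, int]] = []
    for strand in ("+", "-"):
        if strand not in strands:
            continue
        pat = pattern if strand == "+" else revcomp(pattern)
        mism = np.zeros(n_pos, dtype=np.int32)
        for k, allowed in enumerate(_match_matrix(pat)):
            mism += ~allowed[codes[k:k + n_pos]]
        for pos in np.nonzero(mism <= max_mismatch)[0]:
            hits.append((int(pos) % L, strand, int(mism[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def translate(codons: str, table: int = 11, start_is_met: bool = False) -> str:
    """Translate a codon-aligned DNA string; trailing stop is dropped."""
    prot = str(Seq(codons[: len(codons) - len(codons) % 3]).translate(table=table))
    if prot.endswith("*"):
        prot = prot[:-1]
    if start_is_met and prot:
        prot = "M" + prot[1:]
    return prot


def _scan_frames(res: str, min_len: int, table: int, allow_partial: bool):
    """Yield ORFs as (start, end, frame, has_start, has_stop, starts) in local coords."""
    L = len(res)
    for frame in range(3):
        seg_start = frame
        i = frame
        while i + 3 <= L:
            codon = res[i:i + 3]
            if codon in STOP_CODONS:
                yield from _segment_orfs(res, seg_start, i + 3, frame, True,
                                         min_len, allow_partial)
                seg_start = i + 3
            i += 3
        if allow_partial and i > seg_start:
            yield from _segment_orfs(res, seg_start, i, frame, False,
                                     min_len, allow_partial)


def _segment_orfs(res, seg_start, seg_end, frame, has_stop, min_len, allow_partial):
    starts = [j for j in range(seg_start, seg_end - 3 + 1, 3)
              if res[j:j + 3] in START_CODONS]
    if has_stop:
        starts = [j for j in starts if j < seg_end - 3]
    if starts:
        orf_start = starts[0]
        if seg_end - orf_start >= min_len:
            yield (orf_start, seg_end, frame, True, has_stop, starts)
    elif allow_partial and has_stop and seg_end - seg_start >= min_len:
        yield (seg_start, seg_end, frame, False, True, [])


def find_orfs(
    seq: "GenomicSequence | str",
    min_len: int = 150,
    table: int = 11,
    allow_partial: bool = True,
    seq_id: str | None = None,
) -> list[ORFRecord]:
    """Naive six-frame ORF scan.

    ORFs run from the first start codon after the previous in-frame stop to
    the next stop (stop codon included in the interval).  With
    ``allow_partial``, stop-bounded stretches of at least ``min_len`` bp
    lacking any start codon are reported with the 5'-partial flag (mirrors
    array-edge genes with no start codon).
    """
    res = residues_of(seq)
    sid = seq_id or (seq.id if isinstance(seq, GenomicSequence) else "seq")
    L = len(res)
    out: list[ORFRecord] = []
    for strand in ("+", "-"):
        s = res if strand == "+" else revcomp(res)
        for (a, b, frame, has_start, has_stop, starts) in _scan_frames(
            s, min_len, table, allow_partial
        ):
            coding = s[a:b]
            prot = translate(coding, table=table, start_is_met=has_start)
            if strand == "+":
                iv = Interval(sid, a, b, "+")
                cand = list(starts)
            else:
                iv = Interval(sid, L - b, L - a, "-")
                cand = [L - j - 3 for j in starts]
            out.append(ORFRecord(interval=iv, frame=frame, has_start=has_start,
                                 has_stop=has_stop, protein=prot,
                                 candidate_starts=cand))
    out.sort(key=lambda o: (o.interval.start, o.interval.end, o.interval.strand))
    return out


def to_rna(residues: str) -> str:
    """Display transliteration T->U for RNA-facing outputs."""
    return residues.replace("T", "U").replace("t", "u")
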