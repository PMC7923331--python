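"""Alignment statistics for boundary/exon conservation analyses.

Pairwise identity/similarity with blast-like conventions, per-column
information content of a multiple alignment (logo data), and IUPAC
consensus extraction.  Multiple alignments themselves are consumed, not
computed — any aligner's aligned FASTA is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import align as _align
from .errors import InputError
from .seq_core import IUPAC_CODES

_IUPAC_UNION = {frozenset(v): k for k, v in IUPAC_CODES.items()}

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def pairwise_stats(a: str, b: str, mode: str = "global",
                   alphabet: str = "protein") -> tuple[float, float]:
    """(identity %, similarity %) of a pairwise alignment.

    Identity: exact matches over aligned columns, terminal gaps excluded.
    Similarity: columns with a positive BLOSUM62 score (protein); for
    nucleotide input similarity equals identity.
    """
    if not a or not b:
        raise InputError("pairwise_stats: empty sequence")
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be local or global, got {mode!r}")
    protein = alphabet == "protein"
    stats = _align.align_stats(a, b, mode=mode, protein=protein)
    if stats is None:
        return 0.0, 0.0
    return stats.identity, (stats.similarity if protein else stats.identity)


@dataclass
class AlignmentColumnProfile:
    """Per-column residue counts, entropy and information content."""

    index: int
    counts: dict[str, int]
    entropy: float | None      # bits; None for all-gap columns
    information: float | None  # log2(|alphabet|) - entropy


def _guess_alphabet(rows: list[str]) -> str:
    residues = {c for row in rows for c in row if c not in "-."}
    return NT_ALPHABET if residues <= set("ACGTU") else AA_ALPHABET


def column_information(rows: list[str], alphabet: str | None = None
                       ) -> list[AlignmentColumnProfile]:
    """Shannon entropy and information content per alignment column.

    Gaps are excluded from the counts; all-gap columns report entropy and
    information as missing (None).  Information is ``log2(A) - H`` with A=4
    for nucleotides and 20 for proteins (no small-sample correction).
    """
    if not rows:
        raise InputError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise InputError("alignment rows have unequal lengths")
    alpha = alphabet or _guess_alphabet(rows)
    max_bits = math.log2(len(alpha))
    profiles = []
    for i in range(width):
        col = [r[i].upper().replace("U", "T") if alpha == NT_ALPHABET else r[i].upper()
               for r in rows]
        residues = [c for c in col if c not in "-."]
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        if not residues:
            profiles.append(AlignmentColumnProfile(i, counts, None, None))
            continue
        n = len(residues)
        ent = -sum((k / n) * math.log2(k / n) for k in counts.values())
        profiles.append(AlignmentColumnProfile(i, counts, ent, max_bits - ent))
    return profiles


def consensus(rows: list[str], plurality: float = 0.7) -> str:
    """IUPAC consensus: per column, the smallest degenerate code covering
    the most frequent residues whose cumulative frequency reaches the
    plurality; gap-majority columns are emitted as gaps."""
    if not (0.5 < plurality <= 1):
        raise ValueError("plurality must lie in (0.5, 1]")
    if not rows:
        raise InputError("empty alignment")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise InputError("alignment rows have unequal lengths")
    out = []
    for i in range(width):
        col = [r[i].upper().replace("U", "T") for r in rows]
        n = len(col)
        gaps = sum(c in "-." for c in col)
        if gaps > n / 2:
            out.append("-")
            continue
        residues = [c for c in col if c not in "-."]
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        chosen: set[str] = set()
        cum = 0
        for base, k in ranked:
            chosen.add(base)
            cum += k
            if cum / len(residues) >= plurality:
                break
        code = _IUPAC_UNION.get(frozenset(chosen))
        out.append(code if code else "N")
    return "".join(out)


def logo_table(rows: list[str], alphabet: str | None = None
               ) -> list[tuple[int, str, float]]:
    """(column, residue, height) rows for a standard logo renderer, where
    height = residue frequency x column information."""
    table = []
    for prof in column_information(rows, alphabet):
        if prof.information is None:
            continue
        total = sum(prof.counts.values())
        for residue, k in sorted(prof.counts.items()):
            table.append((prof.index, residue, (k / total) * prof.information))
    return table


def write_logo_tsv(path, rows: list[str], alphabet: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("column\tresidue\theight\n")
        for col, residue, height in logo_table(rows, alphabet):
            fh.write(f"{col}\t{residue}\t{height:.6f}\n")


def read_aligned_fasta(path) -> list[tuple[str, str]]:
    """Aligned FASTA reader (ids preserved, rows length-checked)."""
    entries: list[tuple[str, str]] = []
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    entries.append((name, "".join(chunks)))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        entries.append((name, "".join(chunks)))
    if not entries:
        raise InputError(f"{path}: empty alignment file")
    width = len(entries[0][1])
    if any(len(s) != width for _, s in entries):
        raise InputError(f"{path}: aligned rows have unequal lengths")
    return entries
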