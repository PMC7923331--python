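"""Sequence substrate: FASTA I/O, reverse complement, degenerate scanning,
ORF finding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mobscan.errors import AlphabetError, FastaFormatError
from mobscan.seq_core import (IUPAC_CODES, GenomicSequence, find_orfs,
                              iupac_scan, read_fasta, revcomp, translate,
                              write_fasta)

IUPAC = "".join(IUPAC_CODES)


def test_read_fasta_roundtrip_order_and_u_normalization(tmp_path):
    path = tmp_path / "x.fa"
    path.write_text(">a desc\nacguacgu\n>b\nTTTTTTTTTT\n")
    recs = read_fasta(path)
    assert [r.id for r in recs] == ["a", "b"]
    assert recs[0].residues == "ACGTACGT"      # uppercased, U -> T
    assert recs[1].length == 10
    out = tmp_path / "y.fa"
    write_fasta(out, recs)
    assert [r.residues for r in read_fasta(out)] == [r.residues for r in recs]


@pytest.mark.parametrize("content,fragment", [
    ("", "empty"),
    ("ACGT\n", ":1"),           # data before any header names the line
    (">\nACGT\n", ":1"),        # header without an identifier
])
def test_read_fasta_malformed(tmp_path, content, fragment):
    path = tmp_path / "bad.fa"
    path.write_text(content)
    with pytest.raises(FastaFormatError) as err:
        read_fasta(path)
    assert fragment in str(err.value)


@pytest.mark.parametrize("seq,expected", [
    ("ACGT", "ACGT"),           # palindrome
    ("RYY", "RRY"),             # complement table then reversal, by hand
    ("KM", "KM"),
    ("N", "N"),
])
def test_revcomp_examples(seq, expected):
    assert revcomp(seq) == expected


@settings(max_examples=60, derandomize=True)
@given(st.text(alphabet=IUPAC, min_size=0, max_size=40))
def test_revcomp_is_an_involution(s):
    assert revcomp(revcomp(s)) == s


def test_revcomp_rejects_non_iupac():
    with pytest.raises(AlphabetError):
        revcomp("ACX")


@pytest.mark.parametrize("pattern,seq,mm,expected", [
    ("GTTRRRY", "GTTAGGC", 0, [(0, "+", 0)]),
    ("RYYYACC", "GTTTACC", 0, [(0, "+", 0)]),       # R=G, Y=T
    ("GTGYG", "TTGCG", 1, [(0, "+", 1)]),            # one-off boundary variant
    ("GTTRRRY", "ACG", 0, []),                       # pattern longer than seq
])
def test_iupac_scan_examples(pattern, seq, mm, expected):
    hits = [h for h in iupac_scan(pattern, seq, mm) if h[1] == "+"]
    assert hits == expected


def _naive_scan(pattern, seq, strand):
    pat = pattern if strand == "+" else revcomp(pattern)
    hits = []
    for pos in range(len(seq) - len(pat) + 1):
        mism = sum(seq[pos + k] not in IUPAC_CODES[pat[k]]
                   for k in range(len(pat)))
        if mism == 0:
            hits.append(pos)
    return hits


def test_iupac_scan_matches_naive_oracle():
    rng = np.random.default_rng(7)
    for _ in range(100):
        m = int(rng.integers(3, 8))
        pattern = "".join(rng.choice(list("ACGTRYN"), size=m))
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 120))))
        for strand in "+-":
            got = [p for p, s, _ in iupac_scan(pattern, seq, 0) if s == strand]
            assert got == _naive_scan(pattern, seq, strand)


def test_iupac_scan_strand_symmetry():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    pattern = "GTTRRRY"
    minus = {p for p, s, _ in iupac_scan(pattern, seq, 0) if s == "-"}
    plus_of_rc = {p for p, s, _ in iupac_scan(revcomp(pattern), seq, 0)
                  if s == "+"}
    assert minus == plus_of_rc


def test_find_orfs_minimal_start_stop():
    orfs = [o for o in find_orfs("ATGAAATAA", min_len=9) if o.strand == "+"]
    assert len(orfs) == 1
    orf = orfs[0]
    assert (orf.interval.start, orf.interval.end) == (0, 9)
    assert orf.has_start and orf.has_stop and orf.protein == "MK"


def test_find_orfs_startless_stretch_is_five_prime_partial():
    # a 144 bp stop-bounded stretch with no start codon (array-edge gene)
    rng = np.random.default_rng(3)
    codons = [c for c in ("AAA", "CCC", "GGC", "GAA", "CGC", "TGC")]
    body = "".join(rng.choice(codons) for _ in range(48))
    seq = "TAA" + body + "TAA"
    hits = [o for o in find_orfs(seq, min_len=140)
            if o.strand == "+" and not o.has_start]
    assert len(hits) == 1
    assert hits[0].five_prime_partial and hits[0].has_stop
    assert hits[0].interval.length == 147  # stretch plus its stop codon


def test_find_orfs_reverse_strand_retranslation_oracle():
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    for orf in find_orfs(seq, min_len=90):
        sub = seq[orf.interval.start:orf.interval.end]
        coding = sub if orf.strand == "+" else revcomp(sub)
        expect = translate(coding, start_is_met=orf.has_start)
        assert expect == orf.protein


def test_find_orfs_strand_swap_symmetry():
    rng = np.random.default_rng(9)
    seq = "".join(rng.choice(list("ACGT"), size=1500))
    fwd = {(o.interval.start, o.interval.end, o.strand)
           for o in find_orfs(seq, min_len=90)}
    L = len(seq)
    swapped = {(L - e, L - s, "+" if st_ == "-" else "-")
               for s, e, st_ in
               ((o.interval.start, o.interval.end, o.strand)
                for o in find_orfs(revcomp(seq), min_len=90))}
    assert fwd == swapped


def test_genomic_sequence_invariants():
    s = GenomicSequence(id="x", residues="acgtn")
    assert s.residues == "ACGTN" and s.length == 5
    with pytest.raises(AlphabetError):
        GenomicSequence(id="y", residues="ACGT!")
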