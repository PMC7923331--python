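# mobscan

Annotation of **integron-associated mobile genetic elements** in bacterial
contigs and genomes: attC recombination sites and gene cassette arrays
(complete integrons and CALINs), **group II introns** associated with those
arrays, **IS200/605**-superfamily insertion sequences, and the
replication-strand context of all of it. It is written for microbial
genomicists studying how cassette arrays, retroelements and
single-strand-transposing IS elements co-mobilize — e.g. in halophile
genomes and hypersaline metagenome assemblies, where group IIB and IIC-attC
introns turn up inside cassette arrays next to IS605-group elements.

Because curated truth for such composite loci is scarce, the package ships
a synthetic-landscape generator that plants every element family with exact
coordinates (a machine-readable truth ledger beside the FASTA), so the
entire pipeline is validated closed-loop.

## The models in brief

**attC sites.** An attC is modeled as four binding boxes in order
R″–L″–L′–R′, with sequence consensus only on R″ (5′-RYYYACC-3′) and R′
(5′-GTTRRRY-3′). A candidate is accepted when the boxes occur in the right
order and span (40–150 bp default), the antiparallel R″·R′ pairing reaches
6/7 (the R box of the folded bottom strand, one position extrahelical), and
an internal pair of mutually complementary windows forms the L box.
Arrays: ≥ 2 sites whose inter-site gaps are ≤ 8 kb form a locus; a locus
with an intI-integrase-like ORF within 10 kb is a complete integron,
otherwise a CALIN (cluster of attC sites lacking integrase). Cassettes are
the inter-site segments plus a leader.

**Group II introns.** The intron-encoded protein (IEP) is found by local
alignment (BLOSUM62) against a labeled reference panel and its RT0–RT7, X
and En domains are projected through the alignment; the YADD catalytic
motif is checked inside RT5. The ribozyme's 3′ end is the DV/DVI helix
pair downstream of the ORF — DV carrying the catalytic triad AGC (CGC in
group IIC) and an A·Y bulge, DVI a bulged A — followed by the boundary
consensus 5′…AXX(X)XRAY-3′ (with flagged relaxation tiers down to `AY`).
The 5′ end is a GUGYG match (≤ 1 mismatch) anchored by a long-range DI
duplex. EBS1/EBS2/EBS3–IBS target pairing, the DIV basal stem, and the
IIC-attC insertion context (TTGT/T junction inside the attC bottom strand,
orientation opposite to cassette transcription) are reported, and each
intron is called **full**, **5′-truncated**, or **fragmented**.

**IS200/605 elements.** tnpA (HUH transposase) / tnpB homology, grouped
when ≤ 2 kb apart; element ends are the best subterminal palindromic
hairpins within 150 bp of the outermost ORFs (the family has no terminal
inverted repeats). Opposite-orientation tnpA/tnpB with both end hairpins
is the IS605-group signature.

**Replication context.** Given an OriC interval, the terminus is half a
genome away from the OriC midpoint; within replichore 1 (OriC→ter) the top
strand is leading. Features are assigned leading/lagging by midpoint.

## Worked example

Simulate a 100 kb landscape with a complete integron (IIC-attC intron,
IIB intron, toxin–antitoxin cassette), a CALIN with a 5′-truncated intron,
and an IS605 element directly downstream of the CALIN — then annotate it:

```bash
mobscan simulate --seed 42 --out demo/
mobscan run --fasta demo/landscape_42.fasta --out demo_ann/
```

which prints

```
mobscan: wrote demo/landscape_42.fasta with 19 planted features
mobscan: {'n_orfs': 533, 'n_attc_sites': 7, 'n_loci': 2,
          'n_complete_integrons': 1, 'n_calins': 1, 'n_introns': 3,
          'n_is_elements': 1}
```

`demo_ann/report.json` holds the full machine-readable report. For this
landscape it contains two loci — a complete integron (4 attC sites, 4
cassettes) and a CALIN — and three introns:

```
complete_integron [31744, 35888]   CALIN [66573, 67754]
IIC  full                33557..32204   (opposite orientation, TTGT/T junction)
IIB  full                34141..35508   (immediately after an attC site)
IIB  five_prime_truncated      ..67677  (no resolvable 5′ boundary)
IS605_group [67856, 69694] linked to the CALIN
```

All coordinates match the planted truth in `demo/landscape_42.truth.json`
exactly. `demo_ann/annotations.gff3` carries the same features as GFF3
(attC boxes, cassettes, DV/DVI and EBS sub-features, IS ends).

Real assemblies are annotated the same way (`mobscan run --fasta
contigs.fasta ...`, or `mobscan benchmark --accession-dir DIR` for a
directory of user-downloaded FASTA files; the tool performs no network
access). Reference panels are labeled protein FASTAs (`--panel-iep`,
`--panel-inti`, `--panel-tnp`); without them, built-in deterministic
synthetic panels are used — fine for the synthetic landscapes, but real
data needs real panels.

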