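# Methods

This note documents the models, the defaults and why they hold, what the
synthetic landscapes do and do not emulate, and the numerical choices that
keep every call deterministic.

## Coordinates and sequence handling

All internal coordinates are 0-based half-open on the top strand; GFF3
output is 1-based inclusive, with wrapped features on circular sequences
split into two parts sharing an ID. DNA is canonical internally (U→T on
input, logged); display strings facing RNA biology transliterate T→U.
ORFs use bacterial translation table 11 with ATG/GTG/TTG starts; a
stop-bounded stretch with no start codon is reported with a 5′-partial
flag, and all alternative start codons are listed rather than choosing one
(there is no principled rule for picking among them).

## Secondary structure

Folding is **maximum base pairing** (Nussinov dynamic programming) over
Watson–Crick plus G·U pairs with a minimum hairpin loop of 3 — a pair
count, not a thermodynamic model, because every downstream use is
qualitative (is there a helix of the right shape in the right place), and
free energies would add parameters without changing any call. Co-optimal
structures are resolved by a fixed traceback order (j unpaired preferred,
else the smallest pairing partner), which makes the reported structure
deterministic; only `max_pairs` is ever compared against the enumeration
oracle. The stem-loop scanner extends stems outward from every candidate
loop, tolerating up to 2 single-base bulges at 0.5 score penalty each;
hairpin score = pairs − 0.5·bulges.

Box-against-box pairing (`pair_boxes`) is Watson–Crick only by default:
the attC R and L boxes pair as a DNA duplex in the folded bottom strand,
where wobble pairs do not apply. G·U is available by flag for RNA-facing
uses. Under uniform composition the expected random pairing fraction is
exactly 4/16 = 0.25 (6/16 = 0.375 with G·U) — the values the tests freeze,
computed by enumerating the 16 ordered base pairs.

## attC model and defaults

A site is R″(RYYYACC) … L″ … L′ … R′(GTTRRRY) on its coding orientation,
40–150 bp overall. Defaults and their rationale:

* **box mismatch budget 0.** The two box consensi are weak (expected ~1
  match per kilobase each at one mismatch); with a budget of 1 the random
  co-occurrence rate in 100 kb reaches hundreds and no downstream filter
  can restore specificity. At 0 mismatches plus the filters below the
  expected false-positive rate is ~0.003 per 100 kb of random sequence
  (measured 0 in 10 × 100 kb).
* **R-box pairing ≥ 6/7.** Exact consensus instances of the two boxes can
  pair at most 6/7 (position 6 of R″ is structurally extrahelical), so the
  threshold demands the maximum the consensus permits.
* **L box: two 10-nt windows at pairing fraction 1.0**, symmetric arms
  (≤ 5 nt asymmetry) around a 3–30 nt central loop. The L boxes have no
  printed sequence consensus; they are constrained purely by mutual
  pairing and geometry.
* Overlapping candidates are resolved greedily by score then leftmost.

Arrays: single-linkage chaining with inter-site gap ≤ 8,000 bp (gap =
next start − previous end); loci need ≥ 2 sites. Cassettes are the
inter-site segments plus a leader (default 2,000 bp) before the first
site; ORFs are assigned to the cassette containing their midpoint, with a
boundary-spanning flag when they protrude. intI classification is
homology-only: a locus is a complete integron when an ORF within 10 kb of
the array aligns to an intI reference at ≥ 35% identity over ≥ 70% of the
reference; otherwise a CALIN.

The cassette transcription polarity of a locus is defined as the majority
coding orientation of its attC sites (an attC sits at the 3′ end of its
cassette). An ORF-vote definition was rejected: low-complexity coding
sequence creates long spurious reverse-frame ORFs that can flip the vote.

## Group II intron inference

IEP detection aligns every ORF ≥ 50 aa against the labeled panel
(Smith–Waterman, BLOSUM62, −11/−1 gaps) behind a shared-6-mer prefilter
(≥ 2 shared 6-mers) that removes the background ORFs of a 100 kb sequence
without touching genuine hits down to ~50% protein identity. Identity is
matches over aligned columns (terminal gaps excluded); similarity is
positive-scoring columns — blast conventions. Reference domain intervals
are projected through the alignment blocks; a domain is *present* at ≥ 70%
coverage, *partial* at ≥ 15%. ORF fragments of one disrupted frame (same
strand and reference class, ≤ 1 kb apart) merge into one hit whose
`frame_disruptions` counts the joins. Class calls are
nearest-reference-class with a 5-point identity margin, else "ambiguous".

Boundary inference runs in an intron-oriented window around the IEP:

* **3′ end** — within 400 bp downstream of the ORF, the best pair of
  non-overlapping hairpins where DV starts ≤ 60 bp after the ORF (DV sits
  at the base of DIV, which carries the ORF), carries the catalytic triad
  in its 5′ arm (AGC; CGC accepted for IIC) and DVI follows within ≤ 30 bp
  with a bulged A. The terminus is the earliest-ending match of
  A-XX(X)X-R-A-Y after DVI (window 20 nt), with relaxation tiers (`AY`
  2-mer, then any position) each recorded as a deviation. Candidate pairs
  rank by (consensus tier, combined helix score, position): structure
  decides only among candidates of equal consensus support. The DV offset
  bound and tier-first ranking exist because low-complexity coding
  sequence (e.g. most-frequent-codon tracts) folds into long spurious
  helices further downstream.
* **5′ end** — GUGYG matches (≤ 1 mismatch) in 3 kb upstream of the ORF,
  each required to anchor a **DI basal duplex**: a ≥ 11/12 antiparallel WC
  complement of the 12-mer immediately after the boundary within 300 nt.
  Candidates rank by (mismatches, duplex pairs, position). A raw
  max-pairing density score was rejected as the "folds like DI" criterion:
  Nussinov pairing density saturates near its ceiling on arbitrary
  sequence and cannot discriminate. No qualifying candidate ⇒ candidate
  5′ truncation.
* **DIV basal stem** — best antiparallel WC complement (≤ 1 mismatch over
  an 8-mer) of the k-mer immediately 5′ of DV, searched inside the ORF and
  ≤ 200 bp upstream of the ORF start.
* **EBS–IBS** — IBS1 is the last 6 nt of the 5′ exon (4 for IIC, which
  has no IBS2–EBS2 interaction); EBS windows are best antiparallel WC
  complements (≤ 1 mismatch) in the DI region. **EBS3 convention:** the
  base immediately 3′ of EBS1 — the literature gives no searchable
  consensus position for a single base, so the package fixes one and
  reports whether it complements IBS3.
* **Integrity** — *full* iff both boundaries resolved, RT0–RT7 and X all
  present, and no frame disruptions; *5′-truncated* iff 3′ resolved but 5′
  unresolved; otherwise *fragmented*. En is not required (En− IEPs are
  common).

IIC-attC context flags: insertion junction within/immediately at an attC
(≤ 5 bp), attC adjacency (≤ 50 bp), exon junction reading TTGT/T on the
intron strand, and orientation opposite to cassette polarity.

## IS200/605

tnpA/tnpB ORFs (≥ 35% identity, ≥ 50% reference coverage) pair when ≤ 2 kb
apart. Ends are the best hairpins (≥ 6 WC pairs) within 150 bp of the
outermost ORF boundaries. Opposite-orientation tnpA+tnpB with both end
hairpins ⇒ IS605 group; tnpA-only with a single end hairpin ⇒ IS200-like
candidate; anything missing a component or an end ⇒ partial. No
target-site-duplication check: the family neither gains nor loses
nucleotides on insertion. Element comparison reports global nucleotide
identity and per-end stem/loop congruence.

## Replication context

ter = (OriC midpoint + ⌈L/2⌉) mod L; the odd-length remainder goes to
replichore 1. The OriC midpoint (rather than an edge) anchors the
half-genome offset — the choice is arbitrary at ±625 bp on a 2.8 Mb
genome and is made once for determinism. Features are called by midpoint;
features spanning ter are flagged. Calls are invariant under rotation of
the coordinate origin (tested against a rotate-to-origin oracle).

## Synthetic landscapes

The generator emulates composite mobile-element loci: attC arrays built
from exact consensus box instances with perfectly complementary 10-nt L
boxes; cassette ORFs and toxin/antitoxin pairs (random proteins
back-translated with a fixed most-frequent-codon table); a IIC-attC intron
inserted on the bottom strand at a TTGT/T junction immediately 5′ of an
attC R″ box, opposite to cassette orientation; a IIB intron immediately
downstream of an attC in cassette orientation with engineered
EBS1/EBS2/EBS3 complements; a 5′-truncated intron (boundary, DI and the
IEP N-terminus through RT4 deleted); an IS605 element (tnpA ←, tnpB →,
12-bp-stem end hairpins) directly downstream of a CALIN; and uniform point
substitutions applied last. Draw order is fixed — background, plants in
list order, mutation — so a config is byte-reproducible.

Two constructions guarantee *exact-anchor* recovery at mutation rate 0:

* planted hairpins are flanked by AA guards (A·A cannot pair, even as a
  wobble), so detected stem extents cannot extend past the planted arms,
  and L-box/loop boundary bases are drawn non-complementary so the planted
  L windows are the unique perfect pairing (a complementary block is
  otherwise translationally ambiguous);
* after assembly the generator re-runs the local anchor searches
  (boundaries, EBS windows, basal stem, attC boxes, IS ends) and, if any
  random background window ties or beats a planted anchor — a chance
  perfect EBS complement, a spurious GUGYG with a strong duplex in a
  truncated intron's search window — the landscape is regenerated with a
  deterministically salted seed (observed ≤ 2 extra attempts per seed).
  The truth coordinates are fixed by construction; the re-search only
  rejects ambiguous backgrounds, in the same way a synthetic benchmark
  locus would be designed not to contain two copies of its own answer.

What the landscapes do **not** emulate: phylogenetically realistic
divergence (mutations are uniform i.i.d. substitutions; no indels),
metagenomic fragmentation or read noise, divergent attC sites far from the
box consensus, intron tertiary interactions, and real promoter/terminator
context. Passing the closed-loop tests therefore demonstrates correctness
of the algorithms under the stated models, not sensitivity on real
divergent elements — on real data the consensus-anchored attC detector in
particular is conservative, and its budgets are configurable.

Default problem sizes: the standard landscape is 100 kb with two arrays
(19 planted features); recovery acceptance uses 20 seeds. The mutation
sweep uses a compact 30 kb landscape (13 features), 30 seeds per rate —
sizes chosen so the whole validation suite stays desk-scale while every
element family and every decision path is exercised. At the default
thresholds, recovery at exact-anchor stringency degrades steeply with
substitution rate (≈ 50% at 1%, ≈ 30% at 2%, < 10% at 5%): most element
definitions require near-perfect consensus or perfect duplexes, which is
the intended specificity/sensitivity trade at desk scale.

## Reference panels

Panels are labeled protein FASTAs (class labels and domain coordinates in
the header). The built-in panels are **synthetic** — deterministic random
proteins with the documented domain layout and a planted YADD — which
makes the pipeline runnable and testable offline; they are stand-ins with
no biological sequence content, and analyses of real sequence require real
IEP/intI/tnp panels in the same format.

## Known limitations

* attC detection is consensus-anchored; strongly divergent R boxes (which
  profile/covariance models can catch) are missed by design at default
  budgets.
* The 5′-boundary search assumes an intact DI basal duplex; introns with
  heavily eroded DI will be called 5′-truncated.
* Domain projection inherits local-alignment uncertainty at domain edges;
  present/partial thresholds (70%/15%) are heuristic.
* The EBS3 position is a package convention (see above), not an inferred
  structural location.
* Circular-sequence support covers coordinate arithmetic and GFF3
  splitting; detectors scan the linear sequence (features spanning the
  origin of a rotated circular genome should be analyzed after rotation).
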