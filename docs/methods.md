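# Methods

This note documents the models, conventions and numerical choices behind
`dgrhunt`, in the order the pipeline applies them.

## Detection model

A DGR is called from two independent pieces of evidence on one contig: a
reverse-transcriptase-like gene, and a nearby pair of near-identical repeats
whose mismatches are adenine-specific. The pipeline deliberately uses *only*
these two signals; IMH sequence detection, hairpin structure prediction and
Avd identification are out of scope, and ORF membership of the VR is
reported as an annotation but never used as a filter.

### RT search

Contigs are translated in all six frames (standard genetic code; codons
containing N translate to X, stops are retained as `*`). Each frame is
searched as its stop-delimited segments, so an alignment can never cross a
stop codon — the frame search is equivalent to searching every ORF of the
contig. Segments shorter than the minimum that could possibly reach the
score cutoff (score/11, the best BLOSUM62 diagonal entry, with a floor of 12
residues) are skipped; this is purely an optimisation and cannot change the
hit set.

Alignment is Smith–Waterman with BLOSUM62, affine gaps costing
`open + k·extend` for a gap of length k, defaults open 11 / extend 1
(conventional protein-search settings). X scores as the matrix minimum (−4)
against everything. Significance uses the Karlin–Altschul expectation
E = K·m·n·e^(−λS) with the standard gapped BLOSUM62 parameters λ = 0.267,
K = 0.041, m the reference length and n the total translated residues of
the contig; the effective-length correction is omitted. This is approximate,
but only the decision boundary at the conventional cutoff E ≤ 1e-10
matters downstream, and the 1000-decoy calibration (below) shows the cutoff
is conservative there. Overlapping hits to one reference keep the best
score; for calling, hits of different references to one locus are collapsed
likewise.

### Repeat scan

The flank region (RT hit ± 10 000 bp, clipped) is fragmented into 200 bp
windows stepped by 50 bp. All non-overlapping window pairs are compared in
both orientations with a megablast-like DNA alignment (match +2, mismatch
−3, gap open 5, extend 2). Two optimisations keep this quadratic step
cheap without changing results on the repeats of interest: window pairs
sharing no 12-mer (in the relevant orientation) are skipped — a ≥ 50 bp
substitution-diverged homologous stretch at ≥ 80 % identity shares 12-mers
with overwhelming probability — and a score-only pass gates the traceback.

Window matches of one orientation on alignment diagonals agreeing within
±10 bp (the merge tolerance; larger offsets indicate distinct repeats, since
TR/VR divergence is substitution-dominated) are chained, and each chain is
refined to its final extent with a single canonical rule:

* the pair is the **maximum-scoring gapless run** along the best diagonal of
  the chain's neighbourhood (±1 window), under the same +2/−3 scores — the
  local-alignment convention of blast-style searches, which extends through
  a 90 %-identity interior (expected +1.5 per column) and stops within a few
  bases of the homology boundary (expected −1.75 per column in unrelated
  flank);
* both ends are then trimmed to the outermost run of ≥ 8 consecutive
  match columns (`end_anchor`). Score-maximal ends can absorb a few chance
  matches bracketing a chance mismatch just beyond the true boundary
  (a `mismatch, match, match` suffix is net-positive); anchored ends remove
  this boundary noise deterministically, which is what makes the mismatch
  *counts* of a called pair reproducible rather than merely its extent.

Anti-diagonals (inverted orientation) are scanned only up to their
self-pairing centre, so a copy never aligns past its own mirror image and
each inverted pair is reported once, upstream copy first. Pairs shorter than
50 columns or below 80 % identity (gap/N columns excluded) are dropped;
containment- and near-duplicate pairs (both intervals ≥ 0.9 Jaccard) are
deduplicated. The identity threshold of 0.8 is deliberately loose — the
real acceptance rule is the adenine classifier; 0.8 merely bounds the
candidate set.

An exactly equivalent brute-force scan (all diagonals and anti-diagonals,
Ruzzo–Tompa maximal-scoring segments, same anchor rule) lives in the test
suite as an independent oracle; on synthetic contigs the windowed scan
reproduces its pair set exactly. Known limitation: a repeat pair containing
a genuine indel is reported as its best gapless segment (or two pairs)
rather than one gapped pair, and inverted copies separated by less than one
window may be missed.

### Mismatch classification

Alignment columns are typed: **match**; **adenine-variable** (exactly one
copy has A); **non-adenine** (both differ, neither is A); **ambiguous** (gap
or N — excluded from identity and from both mismatch counts, capped at 5 %
of columns). Acceptance requires ≥ 5 adenine-variable and ≤ 1 non-adenine
columns. The two wordings of this rule in circulation differ on whether any
non-adenine mismatch is tolerable; the default honours the operational
"no more than one", and `--strict` enforces zero non-adenine mismatches plus
unanimous polarity.

Adenine-specificity is strand-relative: an element on the reverse strand
shows T-specific mismatches in forward coordinates. Each pair is therefore
typed in both senses (as-is, and with both bases complemented) and the
better-supported sense — more adenine-variable, then fewer non-adenine,
then `+` — is used and recorded. This makes calling invariant under
reverse-complementing the contig.

The TR is the copy carrying the majority of the adenines at
adenine-variable columns (the template is the invariant donor, so its
adenines are what vary in the VR); a unanimous majority sets
`polarity_consistent`, and an exact tie emits both orderings flagged
ambiguous. For inverted pairs the stored alignment already holds the
reverse complement of copy B, so typing needs no special casing.

## Repertoire model

Each template adenine independently becomes any of A/C/G/T in the VR
(retention allowed — TR and VR are only *typically* different); non-adenine
positions are invariant. Per codon, all 4^(#adenines) nucleotide variants
are enumerated and translated; the repertoire is the product over codons of
the count of distinct non-stop residues, reported as an exact integer plus
log10. Stop-producing variants are excluded from the product and flagged.
AAY codons reach exactly 15 residues (the NNY half of the code) with zero
stops, since every stop codon needs A or G at its third position. The report
distinguishes codons containing an adenine from codons whose mutagenesis is
actually non-synonymous, since the two counts differ (e.g. GGA). For a pair,
the TR — the invariant source — is decomposed in the VR's reading frame
(leading offset bases dropped).

## Motif classification

The three AvpA-family motifs `GXXVVVYAH`, `HPXXXPFXG`, `RFXGV` are
fixed-length consensus strings; X is a single-residue wildcard (an X *in the
protein* matches only a pattern X). A protein is AvpA-like iff all three
occur in that order with non-overlapping placements; spacing is otherwise
unconstrained, since only the motifs' order along the chain is conserved
knowledge. The most C-terminal `RFXGV` hit is reported as the candidate
IMH-encoded β5 strand.

## Synthetic data

The generator plants, in order on the forward strand: a variable-protein ORF
(ATG + 6 codons + VR + 6 codons + TAA, stop-free in frame), a perfect
palindromic hairpin (stem 12, loop 6) 30 bp downstream of the ORF, the TR,
and an RT gene (uniform synonymous codon choice, seeded) 300 bp past the TR,
embedded at a random position in i.i.d. background at 40 % GC (AT-rich, as
typical for small archaeal genomes). Defaults: 50 kb contigs, 90 bp TR,
7 adenine + 1 non-adenine substitutions → 91 % TR/VR identity, matching the
~90 % typical of natural elements. TR before or after VR is arbitrary in
nature; the generator fixes one order and detection is verified
order-agnostic by swapping the two copies.

Modelling choices worth noting:

* **IMH/IMH\*** are modelled only as a 20 bp invariant 3' segment shared by
  TR and VR (their internal sequence is unspecified knowledge), and the
  repeat additionally keeps an 8 bp invariant 5' margin
  (`start_margin`) so the planted extent is sharply defined at both ends —
  the counterpart of the detector's 8-column end anchor. Without it, a
  substitution in the first columns would be trimmed off and ground-truth
  mismatch counts would not be recoverable even in principle.
* **Non-adenine substitutions** draw their target from the two non-A bases:
  writing an A into the VR at a non-A template position would be typed
  adenine-variable (on the wrong copy) by the symmetric column definition,
  making the generator's bookkeeping inconsistent with its own labels.
* Substitutions that would create an in-frame stop in the VR are re-drawn.
* **Null contigs** are exact Altschul–Erickson dinucleotide-preserving
  shuffles (uniform Eulerian path via rejection-sampled last-edge
  arborescence) when the requested length equals the source; otherwise a
  first-order Markov sample of the source's dinucleotide transitions.
* The bundled RT reference set (`toy_rt_refs.synthetic.faa`) is **synthetic**
  — two generated ~250 aa proteins at 68 % identity with RT-motif flavour —
  sufficient to exercise the homology search. Real analyses must supply real
  DGR RT references.

What the generator does *not* emulate: sequencing error, multi-copy TR
cassettes, gene-calling artefacts, compositional heterogeneity along a
contig, retrohoming dynamics, or Avd. Passing the synthetic benchmarks
therefore demonstrates the correctness of the procedure's logic and its
calibration on substitution-dominated repeats, not its sensitivity on real
metagenomes.

## Validation study sizes

The acceptance script runs: 20 planted + 20 null 50 kb contigs (recall /
false calls / reverse-complement and copy-swap symmetry); a 6 × 4
substitution-count sweep (adenine 3–8 × non-adenine 0–3, 10 replicates per
cell, 5 kb contigs) checking that acceptance equals the ≥5/≤1 indicator in
every replicate; 50 contigs of 3–5 kb with 0–3 planted repeats against the
brute-force scan oracle; ~43 template suites of 1–4 codons against
exhaustive enumeration; 80 random protein pairs (combined length ≤ 16)
against the brute-force DP; and 1000 dinucleotide shuffles of the toy RT
gene as E-value decoys. The pytest acceptance tests run the same checks at
reduced sizes (8+8 benchmark contigs of 20 kb, 2 sweep replicates per cell,
12 oracle contigs, 300 decoys) chosen to keep the full suite under two
minutes.

## Conventions

Coordinates are 0-based half-open everywhere internally; GFF3 output is
1-based inclusive. TSV outputs carry the serialized configuration and its
hash as `#` comment lines. All randomness flows from explicit integer
seeds through `numpy.random.default_rng` (generator, shuffles) or
`random.Random` (test suites); identical configuration and seed give
byte-identical outputs, and contigs are processed independently so
execution order cannot matter.
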