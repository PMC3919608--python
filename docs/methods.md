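# Methods

`cfampol` reconstructs, as a tested pipeline, the comparative analysis of
bacterial replicative DNA polymerase III α-subunits (PolIIIα, the C
family): candidate detection in proteomes, nonredundant genome
selection, domain-architecture annotation, functional-motif analysis,
isoelectric points of the conserved core, classification into the
PolC / DnaE1 / DnaE2 / DnaE3 groups, and genome-level statistics linking
polymerase repertoires to genome size, GC content and oxygen use.

## Profile model and scanning

Reference multiple alignments (one per structural domain, one for the
conserved detection region, one for the PHP–Pol3–(HhH)₂ core) are turned
into position-specific log-odds profiles. Columns with ≥ 50% gaps are
dropped; per-column scores are

    s(c, a) = log2( (f(c, a) + w·bg(a)) / (1 + w) / bg(a) )

with observed residue fraction `f`, pseudocount weight `w` (default 0.5
when building library profiles, 1.0 for ad-hoc profiles) and background
frequencies `bg` (flat 1/20 by default; `X` always scores 0 bits).
Scanning is local Smith–Waterman alignment of the profile against the
protein with affine gaps (open 11, extend 1, in bits — classical
protein-search defaults; the original search tool's parameters are not
published, so these are explicit substitutes). The kernels are
numba-compiled and validated in the test suite against an independent
pure-Python dynamic program.

### Significance

Two routes are provided.

* `empirical_pvalue` — the exact permutation test: the target sequence is
  residue-shuffled `n` times and `p = (1 + #{shuffled ≥ observed}) / (n+1)`.
  This is the reference definition, exercised at unit scale.
* `ProfileCalibration` — for cohort-scale work. For each profile a
  Gumbel null is moment-fitted once to maximal scores of 80 seeded
  random background sequences of length 400, with the location shifted
  by `β·ln(L/400)` for other sequence lengths (Karlin–Altschul-style
  scaling). The same numeric threshold (p ≤ 1e-3) is applied. The two
  routes agree on accept/reject decisions far from the threshold —
  planted domains score hundreds of bits above the null — and the
  calibrated route makes a 100-genome cohort run in seconds rather than
  hours. Detection additionally requires ≥ 40% of profile columns
  covered, and domain hits must show ≥ 10% identity to the profile
  consensus over aligned columns.

## Detection, deduplication

Candidates are the proteins whose best local hit against the conserved
polymerase-region profile passes the thresholds above; one best hit per
protein. The nonredundant genome set follows the pairing rule: two
genomes collapse only when they encode the same number of polymerases
and a count-preserving matching exists with every matched pair > 90%
identical (global alignment, BLOSUM62, identity normalised by the
shorter sequence — the clustering-tool convention). Genomes with
different counts are always both kept. Multi-way redundancy is resolved
through connected components of the pairwise-equivalence graph; the
lexicographically smallest genome id survives. An 8-mer sharing
pre-screen (threshold 0.2) skips alignments for pairs that cannot reach
90% identity; pairs ≥ 90% identical share ~43% of 8-mers while ≤ 80%
pairs fall below ~17%, so the screen is conservative.

## Domain architectures

Each candidate is scanned with all nine domain profiles (PHP, Pol3, HhH,
OB, CTD, NTD, Exo, UDG, Lar), iteratively with hit masking so repeated
copies are found. Non-nested overlaps exceeding 30% of the shorter hit
keep only the higher bit score; an Exo hit at least 90% contained in a
PHP hit is retained as the PolC-hallmark insertion and rendered
`PHP(Exo)`. An Exo hit ending upstream of PHP (linker ≤ 100 residues)
marks the N-terminal exonuclease variant. Unassigned spans ≥ 50 residues
are reported.

Terminal unassigned spans are re-examined by gradual extension: the
terminal 50 residues (or the whole span if shorter) are scanned against
all candidate profiles, growing inward in 25-residue steps. A domain is
accepted only when its assignment probability is ≥ 0.90 while every
other candidate stays ≤ 0.30. The assignment probability is a logistic
transform `σ((z − 8)/1.2)` of the calibrated null z-score, placed so
random spans score < 0.05. Because the same scanner serves both stages,
this stage is a second chance for spans lost to conflict resolution, not
a more sensitive homology detector (the extra sensitivity of HMM–HMM
comparison is deliberately out of scope).

The conserved core — the PHP–Pol3–(HhH)₂ span, the analog of residues
6–889 of the *E. coli* DnaE1 exemplar — is extracted through the
alignment traceback as a map from reference core columns to protein
positions. Core length (matched columns) and core pI are computed on
this subsequence, matching the core-only convention of the length and
charge analyses.

## Motifs

* **Active site.** The three catalytic aspartates (*E. coli*
  D401/D403/D555 equivalents) are checked through the core column map;
  an unmapped column counts as absent. Proteins without the intact triad
  are dropped, mirroring the curation rule for fragments.
* **PHP metal site.** Nine metal-coordinating positions are scored
  against per-group consensus residue sets shipped as configuration
  (the positions are figure-derived in the original analysis, so the
  bundled config is a reconstruction; for synthetic libraries it is
  generated alongside the reference alignments). The site is "intact" at
  a score ≥ 8 of 9.
* **β-clamp motif.** Every pentapeptide from the (HhH)₂ end to the next
  assigned domain start (cap 200 residues; the final 200 residues as a
  flagged fallback when no HhH was assigned) is classified by the rule
  table: positions 4–5 must be `L[FL]` for any class; `Q` at position 1
  gives canonical, upgraded to canonical_strong by `S/D` at position 3
  (the QL[S/D]LF consensus); `P` at positions 1 or 3 marks the
  DnaE2-type motif; anything else with the `L[FL]` anchor is weak. A
  QLPLxL extension is annotated as Hda-like, not a separate class.
* **DnaE2 tail.** `SRDF[H/R]` within the final 15 residues ("very
  C-terminus" made concrete).
* Motif cohorts are summarised as position frequency matrices (rows sum
  to 1 including the gap fraction), the text form of a sequence logo.

## Isoelectric points

Henderson–Hasselbalch net charge with a configurable pKa table
(Bjellqvist-style defaults: D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98,
K 10.0, R 12.0; termini 7.5/3.55), both termini included. The pI is
found by bisection on pH 0–14; the interval is narrowed to 1e-7 pH so
the result is grid-exact to < 1e-3 (a charge-only stopping rule of 1e-4
would leave ~2e-3 pH error on shallow titration curves).

## Group classification

Ordered rules on the feature vector, architecture first:

1. OB upstream of PHP, an NTD, or the Exo insertion → **PolC**.
2. No CTD and (SRDF tail or DnaE2-type clamp motif) → **DnaE2**.
3. Intact PHP site and canonical/canonical_strong clamp → **DnaE1**;
   also disrupted PHP with canonical_strong clamp and CTD → **DnaE1**
   (the proteobacterial pattern of a degraded metal site behind an
   otherwise typical replicase).
4. Disrupted PHP site and weak/absent clamp → **DnaE3**.
5. Otherwise **DnaEX**.

DnaEX fallbacks are re-examined against a neighbor-joining tree over the
column-aligned cores of the queries plus labelled anchor sequences
(Kimura-corrected p-distances, clamped at p ≈ 0.85; negative NJ branch
lengths clamped to 0; column-bootstrap supports, 100 replicates by
default). Clades are evaluated as bipartitions so the arbitrary NJ
rooting is irrelevant: the smallest split side with > 50% support
containing the query and at least one anchor decides, by anchor
unanimity. Supports on zero-length internal edges are set to 0, so
degenerate (identical-sequence) alignments yield no supported clade.
Rule-confident calls are never overridden; in cohort runs the remaining
ambiguity concentrates in exactly the cases the rules cannot separate —
DnaE2 without either hallmark, and strong-motif DnaE3 — mirroring the
acknowledged fuzziness of the DnaE1/DnaE3 boundary.

Maximum-likelihood inference, substitution-model selection and the
original tree search are deliberately not reproduced; NJ+bootstrap is a
desk-scale stand-in documented as such.

## Genome-level statistics

Combination labels use the canonical order PolC, DnaE1, DnaE3, DnaE2,
DnaEX with `m×` multiplicities. Cohort tables report one-decimal
percentages with half-up rounding (the printed style; note 386/945 is
40.8 at one decimal and 41 at integer precision). Trait-binned fractions
collapse combinations into {DnaE1 only, DnaE1 + DnaE2, PolC + DnaE3,
PolC + DnaE1, other}; default bin edges are 1-Mb steps (0–10 Mb) and
5-point GC steps (20–80%), figure-style choices since exact edges are
not printed. Oxygen classes collapse to oxygen-using (aerobe,
facultative, microaerophile) vs anaerobe vs unknown. Correlations are
tie-corrected Spearman coefficients.

## Synthetic cohorts

The generator is the package's study-conditions module, not a test
fixture; its defaults encode the cohort structure the analysis assumes.

* **Domain library.** Nine random blocks (defaults: PHP 270, Pol3 460,
  HhH 100, OB 100, CTD 120, NTD 210, Exo 180, UDG 160, Lar 70 residues;
  all configurable) redrawn until mutually dissimilar (< 20% ungapped
  identity; chance level 5%). Reference alignments hold 8 sequences at
  10% divergence; per-group templates diverge 12% from the consensus, so
  groups are phylogenetically separable while sharing one detection
  profile. Motif columns (active-site D's at fixed relative positions in
  Pol3; the nine PHP positions with canonical residues HHDHEHDHD) are
  planted in the consensus and spared from mutation.
* **Architectures.** Canonical per-group domain orders with 5–20-residue
  random linkers; variant frequencies follow the reported architecture
  survey (PolC without the Exo insertion 6%; DnaE1 typical 93%, no-CTD
  4%, N-terminal-Exo 3%; DnaE3 full 70% / no-CTD 20% / no-OB-no-CTD 10%;
  DnaE2 never with CTD, no-OB 10%).
* **Motifs.** Clamp pentapeptides drawn per group (PolC QLSLF 98%; DnaE1
  canonical_strong 60% / canonical 39% / none 1%; DnaE2 proline-type 75% /
  weak 10% / none 15%; DnaE3 weak 61% / canonical QM·LF 14% / none 25%);
  SRDF[H/R] tail on 77% of DnaE2s; PHP site intact for PolC always,
  DnaE1 70%, DnaE2 10%, DnaE3 never. Planted motif residues are
  mutation-protected by default (`corrupt_motifs` disables this for
  negative tests), so divergence stresses detection rather than truth.
* **Genomes.** Base scenarios {single-DnaE1-type 76.6%, PolC+DnaE3
  15.0%, PolC+DnaE1 8.4%} — the major printed combination fractions
  renormalised. GC ~ U(25, 75)%; size log-uniform 0.5–10 Mb
  (independent, by design decision). DnaE2 presence in DnaE1-type
  genomes is Bernoulli with logit −0.8 + 1.1·GC_std + 0.7·log-size_std +
  0.9·[oxygen-using], copy number 1/2/3 with probabilities
  0.855/0.121/0.024; PolC+DnaE1 genomes are anaerobes with probability
  0.85, PolC+DnaE3 genomes oxygen-using with probability 0.85.
* **Core-length coupling.** DnaE2 and DnaE3 cores are shortened by a
  deletion in a designated Pol3 'thumb' window (never touching the
  distal catalytic aspartate). For DnaE2 the deletion is
  `70 − 1.2·(GC − 50) + ε` residues; the noise σ of ε is solved from the
  requested Spearman target via the bivariate-normal relation
  ρ = (6/π)·asin(r/2), so the planted core length–GC correlation hits
  `rho_target` (default 0.6) in expectation. DnaE3 deletions are
  uniform 0–100, uncoupled.
* **Decoys.** Three random background proteins of 120–600 residues per
  genome.

What the generator does **not** emulate: real amino-acid composition and
substitution structure (mutations are uniform over 20 letters),
insertions/deletions outside the thumb window, inteins, fragmented
genes, shared evolutionary history within groups beyond the star-like
template→sequence divergence, taxonomic structure, and plasmid
localisation. Passing cohort tests therefore demonstrates that the
pipeline's logic recovers planted structure under realistic divergence
and decoy load — not that thresholds are optimal for real proteomes.

## Problem sizes and determinism

Default verification cohorts are 100 genomes (≈ 170 polymerases + 300
decoys) for recovery and 10 × 200 genomes for parameter recovery —
sizes chosen so the whole suite re-runs in minutes on one CPU while
leaving binomial error well inside the asserted margins. All randomness
flows from explicit seeds (NumPy `default_rng`); seeded reruns are
byte-identical across every TSV/JSON output, which the tests assert.

## Known limitations

* Classification accuracy is bounded by the rule set: a DnaE2 lacking
  both the tail and the proline motif is indistinguishable from DnaE3 at
  the feature level (≈ 6% of DnaE2s under the default motif
  frequencies); the clade tie-breaker only repairs fallback calls, by
  design.
* The calibrated p-value extrapolates a Gumbel tail from 80 null
  samples; at p = 1e-3 the extrapolation error is irrelevant for the
  hundreds-of-bits separation of true hits but would matter for
  marginal hits on real data.
* Identity normalised by the shorter sequence inflates with length
  mismatch (0.3–0.4 between unrelated sequences), which is why library
  dissimilarity is certified ungapped.
* NJ over Kimura distances is a topology-level stand-in; branch lengths
  and deep-node supports are not comparable to maximum-likelihood
  results.
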