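# Methods

`gmdomains` implements a desk-scale, fully testable version of a remote-
homology discovery pipeline for genome-maintenance (GM) protein domains:
candidate proteins are compiled from Gene Ontology annotation, interaction
data and co-expression, and their sequences are pushed through masked,
iterative profile-HMM searches against a domain-family library with
reciprocal validation. Every stage can be driven by synthetic inputs with
machine-readable ground truth, so sensitivity, false-positive control and
curation stability are measured rather than assumed.

## Candidate compilation

**Ontology.** The candidate universe pools, across species, proteins
annotated with any of four GM terms: DNA repair (GO:0006281), DNA damage
response (GO:0006974), cytokinesis (GO:0000910) and mitotic cell cycle
(GO:0000278). Before pooling, each term of interest is propagated: a protein
directly annotated only with a descendant (via `is_a` edges) of a term of
interest gains that term. Propagation is monotone and idempotent; only
`is_a` edges are traversed (a conservative closure — `part_of` is not
modelled). Propagation is applied to all four terms by default
(configurable); the interaction filter below only consults the two DDR
terms, so the extra propagation is harmless there and keeps the two
compilation routes consistent.

**Interactions.** From an interaction table, a pair survives when (i)
exactly one side carries GO:0006281 while the other carries neither
GO:0006281 nor GO:0006974 — the DDR-naive side becomes the candidate; (ii)
the record has experimental evidence *and* at least two publications with
experimental evidence; (iii) the candidate is on neither the housekeeping
nor the recurrent-contaminant list. The filters are pure row predicates, so
the surviving set is order-invariant; the order asymmetry → evidence →
lists is fixed only to make the per-stage attrition funnel reproducible.
Duplicate (a,b)/(b,a) records are canonicalized by sorted id before
counting. The two-publication threshold reads the supplied integer field as
given.

**Co-expression.** Per tissue, genes are correlated (Pearson, zero-variance
genes dropped), modules are detected, all within-module pairs are
enumerated, and pairs must recur in at least two distinct tissues
(pair-level recurrence — the literal reading of the protocol). The
surviving pairs then pass the same asymmetry and list filters; the
publication clause is vacuous because co-expression pairs carry no
publication metadata. The module detector is deliberately pluggable: the
default declares each connected component of the `|r| >= r_min` graph
(defaults `r_min = 0.6`, minimum size 5) a module, because downstream only
consumes modules as opaque gene sets. No normalisation or variance
stabilisation is applied to the expression matrix — it is taken as given.
Per-gene signatures rank co-expressed genes by the arithmetic mean of
per-tissue Pearson r, ties broken by gene id.

## Masking

Queries are masked before any search. Coiled coils are detected by a
COILS-style scan: a 20×7 position-specific propensity table is scored as a
(weighted) geometric mean over windows of 14/21/28 residues, maximised over
the seven heptad frames and the windows covering each residue, and
converted to a probability by a two-Gaussian (coiled-coil vs globular)
posterior with a globular prior weight of 30. The weighted variant
up-weights the hydrophobic-seam positions a and d by 2.5. The propensity
table is a documented synthetic stand-in derived from helix/coiled-coil
residue preferences (the original COILS matrix is not redistributed);
consequently every test of this module is relative (heptads vs shuffles,
planted features vs background), never an absolute score comparison. The
Gaussian parameters were calibrated once on ensembles of ideal heptads and
i.i.d. background sequence and are frozen in the source.

Low-complexity tracts are masked by windowed Shannon entropy (window 12,
threshold 2.2 bits, following common SEG-style conventions), taking each
residue's minimum entropy over covering windows. Disorder is approximated
by the low-complexity mask; a dedicated disorder predictor is out of scope.
A residue is masked at coiled-coil probability ≥ 0.5. Searchable regions
are the complement of the mask union with fragments shorter than
`min_region_length` (default 30 in the pipeline) dropped and logged; masked
plus searchable residues partition the sequence up to those logged drops.

## The profile-HMM engine

The engine is a local-alignment profile HMM: M match states with
position-specific emissions, insert states emitting the background
composition, and delete states. Architecture choices, made for closed-form
testability rather than Plan7 fidelity:

- entry into any match state at any target position with probability
  `1/(M·L)`;
- a per-state exit probability (`0.02` from internal match states, 1 from
  the last), folded into the outgoing transition normalisation.

With this normalisation the forward score is a genuine log-likelihood ratio
of two proper sequence distributions, so a model whose emissions equal the
background can never score above 0 bits — a property the tests assert and
the free-end alternative would violate.

Scores are log2 odds against the i.i.d. background. A single fixed
background vector (default uniform 0.05) is shared by the generators and
the engine, closing the loop between simulation and scoring. Non-canonical
residues (B, Z, X, U, O) emit as background — logged, never an exception.

**Estimation from an MSA.** Columns with gap fraction strictly below 0.5
become match states. Emissions use Henikoff position-based sequence weights
(normalised to sum to one) with background-proportional pseudocounts
`α·f[a]`, `α = 1` by default. Transitions come from weighted state-path
counts over each row's residue span with a small additive smoothing of 0.02
per category. Because the sequence weights sum to one, a unit pseudocount
would swamp the data (driving match-match continuation towards 1/3 and
costing ≈1 bit per aligned column); the light smoothing keeps a
single-sequence model's match-match probability near 0.95 while still
regularising deep alignments. Transitions into dead-end states at the final
column (a last-column delete or a post-final insert) are excluded at
normalisation time.

**Profile-profile comparison** aligns match columns of two models under the
co-emission log-odds column score `S(i,j) = log2 Σ_a e_q[i][a]·e_t[j][a] /
f[a]` with affine gaps (open 3 bits, extend 0.3 bits), Smith-Waterman
local. This preserves the column score that defines profile-profile
comparison while omitting the five-pair-state machinery of full HH-style
aligners; the upgrade path is isolated behind the operation interface.
There is no secondary-structure term.

**E-values.** Significance is empirical: optimal-alignment (Viterbi) scores
of i.i.d. background decoys, lengths resampled from the target set, are fit
with a Gumbel by maximum likelihood, and `E(s) = n_db · P(S ≥ s)` under the
fit. Viterbi (max-type) scores are the statistic calibrated because the
Gumbel is their natural asymptotic family; forward scores are exposed but
significance is Viterbi-based. With the transition smoothing above, decoy
score distributions show a stable exponential tail (λ ≈ 0.8 bits⁻¹ for a
100-state family profile) and the plain MLE fit reproduces held-out tail
probabilities at the 0.1/0.01/0.001 levels within binomial error. For
profile-profile searches the decoys are synthetic families of the same
shape as the library (same member count, length and divergence) with
unrelated ancestors. Two exact caching identities speed up large runs
without changing results: under a uniform background, the decoy score
distribution of a single-sequence profile depends only on its length, so
such calibrations are shared per length.

## The discovery pipeline

Per query: mask → for each searchable region, iteratively build an MSA
against a sequence database (single-sequence profile first, include targets
with E ≤ 0.01, realign them master-slave via the Viterbi trace, rebuild,
up to 3 iterations or fixpoint — rows are only ever added) → build the
query profile → profile-profile search against the family library →
reciprocal validation of the best forward hit: a profile seeded from the
hit's family-MSA region is searched back against the full query collection,
and the candidate is `validated` iff a reciprocal hit with E ≤ 0.01 covers
at least half of the forward query region on the original query protein and
the query's best forward family equals the hit family. The reciprocal
threshold mirrors the MSA-inclusion cutoff (the source protocol states no
separate number), and the reciprocal target set is exposed as a parameter.

**Curation.** Any candidate's query MSA can be re-curated — diversity
filter to the 30 most mutually dissimilar rows (greedy maximin, master
always kept, ties by row order), removal of insert columns relative to the
master, then removal of fragment rows (<10 residues) and sparsely covered
columns (<50%) — and the forward plus reciprocal searches re-run. Column
removal is tracked through a column-provenance map so candidate coordinates
remain correct after curation; on clean synthetic alignments curation
re-detects every previously validated family, which the acceptance suite
checks at 100%.

**Descriptive outputs.** Percent-identity (PID) distance trees use
`d = 1 − identity` over co-aligned columns (a pair with no shared columns
gets d = 1, logged) and average-linkage clustering; branch lengths are half
the merge-height differences, making the dendrogram ultrametric by
construction. Pairwise percent identity between two sequences uses one
optimal global alignment (BLOSUM62, gap open 10, extend 0.5) and counts
identical columns over alignment columns, excluding terminal-gap overhangs.

## Synthetic data and what it does and does not show

Families evolve from a random ancestor by i.i.d. per-site substitution
(probability `1 − target_identity`, replacement drawn from the background,
so ~5% of substitutions silently restore the ancestral state) and
Poisson-many indel events of geometric length (mean 2) placed uniformly.
There is no rate matrix, no site-rate heterogeneity, and no tree-aware
evolution — divergence is star-shaped around the ancestor. Planted
coiled-coils are heptad repeats with hydrophobic a/d seams; low-complexity
features are runs over at most three residue types; decoys are pure
background. Expression modules share one latent factor per tissue so the
expected within-module Pearson correlation equals ρ exactly; background
genes are independent noise. Interaction tables carry sampled evidence sets
and publication counts.

Because the same background drives simulation and scoring, the measured
sensitivity/false-positive numbers certify the machinery — the scoring,
calibration and validation logic — under the stated divergence, not
performance on real proteomes, where composition bias, repeats and domain
architecture complexity are harsher. The reference study's database-derived
counts depend on specific, unversioned database releases and are not
reproduction targets here.

## Benchmark study conditions

The planted-domain benchmark uses 8 families of 100-residue domains with 30
library members at target identity 0.4 (realized member-to-ancestor ≈ 0.43,
member-to-member ≈ 0.2 — genuinely remote homology) and indel rate 0.02;
per family 5 additional held-out members are planted into query proteins
between background linkers of 30–70 residues (40 positive queries), plus
200 background decoy queries of 160–240 residues. The MSA-building pool
contains the 240 library-member domain sequences plus 60 background decoys.
A positive counts as recovered when a validated candidate names the planted
family and at least half of the called region lies inside the planted
interval (calls are conservative cores of the domain, so localization of
the call — not coverage of the full domain — is scored); a decoy with any
validated call is a false positive. Across 20 seeds the suite requires
sensitivity ≥ 0.85 and decoy false-positive rate ≤ 0.01 in at least 19.
The E-value calibration check uses one 100-state family profile, 20,000
calibration decoys and 10,000 held-out decoys of 200–800 residues — the
large calibration sample keeps fit variance well below the held-out
binomial noise that the confidence-interval check is designed for.

These sizes keep the full suite and the acceptance script each within a few
minutes on one CPU; the acceptance script averages the benchmark over 5
seeds and reports means.

## Known limitations

- The local-model architecture is not Plan7; scores are not comparable to
  HMMER bit scores.
- The coiled-coil table is a stand-in; absolute probabilities are not COILS
  probabilities.
- The module detector is a correlation-graph component finder, not a
  soft-threshold WGCNA-style method; it is adequate for the pair-mining
  role modules play here and replaceable via the `detector` hook.
- Reciprocal validation searches the query collection; validating against
  an external profile database instead is a parameter change, not a code
  change.
- Pairwise identity is reported from one optimal alignment; co-optimal
  alignments could differ in the excluded-overhang convention at the 0.1%
  level.
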