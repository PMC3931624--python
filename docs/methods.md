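# Methods

This note documents the models, conventions and design choices behind
`pvrda`, the way a statistics package documents its estimators: what
is computed, under which assumptions, with which defaults, and what
the synthetic experiments do and do not demonstrate.

## Data model

A study consists of a rooted phylogeny with non-negative branch
lengths (Newick; polytomies and zero-length branches allowed), a
species × binary-trait matrix (0/1/NA) and a species × predictor table
(one categorical habitat factor plus continuous elevation and height).
Species names are matched across files after trimming whitespace and
treating underscores as spaces (the Newick convention); any species
set mismatch is an error that lists the offending names. Missing
branch lengths are an error by default because every downstream
quantity depends on them; an explicit `missing_length="zero"` opt-in
substitutes zero with a warning.

## Parsimony signal

Steps are counted by the unit-cost minimum-change dynamic program for
two states (`cost[v][s] = Σ_c min(cost[c][s], cost[c][1−s] + 1)`),
which is exact for arbitrary out-degree. On bifurcating trees it
coincides with Fitch counting; we do not use the common
intersection/union fold on polytomies because it can undercount there
(the randomized suite checks exact agreement with exhaustive
minimisation on trees up to 8 tips). Missing tips carry the full
ambiguity set {0, 1} and never add steps.

Per character: M = 0 for constant characters, else 1; G = the smaller
observed state count (the step count on a star tree), computed from
non-missing tips only so that M ≤ S ≤ G always holds; RI = (G − S)/(G
− M). Characters with G = M (constant or autapomorphic) have no
retention information: their RI is undefined (NaN, no exception) and
the ensemble RI — (ΣG − ΣS)/(ΣG − ΣM) — is taken over informative
characters only, with the exclusion count reported. Real anatomical
matrices contain near-constant characters, so silently erroring on
them would be wrong; reporting the exclusion count keeps both
conventions reconstructible.

## The asymmetric Mk2 model

States {0, 1} evolve by a continuous-time Markov chain with gain rate
q01 and loss rate q10 per unit branch length. With s = q01 + q10 and
stationary frequencies (π0, π1) = (q10/s, q01/s) the transition matrix
over a branch of length t is

    P(t) = [[π0 + π1 e^{−st},  π1 (1 − e^{−st})],
            [π0 (1 − e^{−st}), π1 + π0 e^{−st}]],

verified in the tests against the matrix exponential of the generator.
Zero-length branches give the identity (no change possible on them).

**Likelihood.** Felsenstein pruning with per-node rescaling (log
scale factors accumulated), vectorised across characters so that a
pooled fit over hundreds of characters costs one postorder sweep per
likelihood evaluation. Missing tips contribute the partial likelihood
(1, 1) rather than being dropped, so one tree serves all characters.
The root is weighted by a flat prior (0.5, 0.5) by default — matching
the proportional-likelihood reporting convention of Mesquite-style
reconstructions — with the stationary prior available by flag. A
variable character under q01 = q10 = 0 has zero likelihood; −∞ is
returned rather than raising.

**Rate estimation.** The likelihood is maximised over (log q01, log
q10). Likelihood surfaces of asymmetric-rate models are often ridged,
so the fit is a deterministic multi-start: a 5 × 5 grid spanning
[10⁻³, 10²] per unit tree height is evaluated, Nelder–Mead simplex
runs start from the best three grid points, and the best endpoint
wins. Constant characters drive a boundary fit (the rate away from
the observed state → 0) and are flagged degenerate. `shared=True`
pools all characters under one rate pair (product likelihood).

**Marginal ancestral states.** The up–down (outside) pass makes every
internal node's state probabilities conditional on all tips, not just
its subtree; node marginals are normalised to proportional
likelihoods PL0 + PL1 = 1. A node is *unequivocal* when
|log L(0) − log L(1)| reaches the decision threshold T. The default
is T = 2.0 natural-log units (the Mesquite convention); analyses that
use a looser threshold of 1.0 simply pass `--threshold 1.0` — both
are supported because published work is not always explicit about
which was used.

## Phylogenetic correction (PVR + partial RDA)

**PCoA.** The patristic distance matrix D is squared entrywise (no
0.5·d pre-scaling — dialects differ, so this is stated explicitly),
double-centred to −½·J·D²·J, and eigen-decomposed. Axis k is scaled
so its squared coordinates sum to λₖ. Tree metrics are generally not
Euclidean-embeddable, so negative eigenvalues occur; they are dropped
by default and their magnitude share logged, because covariate use
only needs real coordinates. A Lingoes correction (adding 2c to all
squared off-diagonal distances, c = −λ_min) is available behind a
flag for sensitivity analysis.

**RDA / partial RDA.** Responses are centred (standardisation is a
flag; 0/1 traits already share a scale, and the source analyses do not
state their scaling, so both are available). With covariates W, both
the responses and the design are replaced by their least-squares
residuals on [1, W]; the constrained variation is ‖P_X Y‖²_F with P_X
the orthogonal projector onto the (residualised) design, computed via
SVD with a relative rank tolerance plus an absolute floor tied to the
pre-residualisation design scale (so a design annihilated by the
covariates has rank 0, not numerical-noise rank). Factors are coded
as full centred indicator blocks — the pseudo-inverse projection
handles the deliberate rank deficiency and avoids arbitrary
reference-level choices in centroid scores. Explained fractions are
reported against both the pre-covariate and post-covariate totals.
The implementation is checked against vegan's `rda` on a fixed
fixture and against the closed-form R² in the single-response,
single-predictor case.

**Permutation tests.** pseudo-F = (SS_exp/q)/(SS_res/(n−1−q−c)) with
q, c the effective ranks of design and covariates. The null is
generated by permuting the reduced-model residuals of Y (fitted
values from [1, W] held fixed) — the standard scheme for partial
constrained ordination; free permutation of raw rows is a flag. p =
(1 + #{F* ≥ F})/(1 + nperm), 1999 permutations by default for final
tests. The permutation loop is a single tensor contraction over the
stacked permuted responses, which is what makes the calibration
experiments (thousands of tests) affordable.

**Forward axis selection.** At each step the remaining axis that adds
the most explained trait variation (given the already-selected axes as
covariates) is tested; it is admitted at p ≤ α (default 0.05, 999
permutations) and selection stops the first time the best candidate
fails — the standard forward-selection reading. Two guards keep the
procedure sane for single-trait responses: at most n − 3 axes can be
selected (so downstream partial tests retain residual degrees of
freedom), and selection stops when the cumulative R² reaches 1 (an
exhausted residual would make every further F infinite and admit
axes forever). Rows are sorted by species label internally, making
the selection exactly invariant to a joint row permutation of its
inputs. Step seeds derive from the selector seed by step index.

**Evol/Ecol partition.** Per trait: Evol% is the R² on the selected
axes × 100; the ahistorical (AH) test relates the trait to one
predictor alone; the phylogeny-corrected (PC) test conditions on the
axes; Ecol% is the PC model's explained share of the trait's *total*
(pre-covariate) sum of squares, so Evol% + Ecol% cannot exceed 100
within one predictor's partition. Species with a missing value for a
trait are dropped from that trait's tests; the global ordination
instead drops traits missing above 20% (configurable) and
mean-imputes the remainder, with every such decision logged.
Bonferroni families are one (predictor × correction-mode) column
across the reported traits — the reading that keeps the AH and PC
columns internally comparable; family sizes are recorded in the
report metadata. Rendering follows the conventional table style:
adjusted p ≥ 0.10 prints "ns", smaller values print with three
decimals (0.0004 → "0.000", never a bare "0").

## Synthetic data generator

The generator emulates the structure such comparative studies assume,
at their scale: 39 tips, 49 traits, an 8-level habitat factor,
elevation 20–3000 m, height 5–100 cm.

* **Trees** are pure-birth with unit birth rate. The process is run
  past the n-th speciation by one exponential waiting time so no
  terminal branch has length zero (a zero-length cherry split by a
  trait would otherwise have zero likelihood under any rates), then
  rescaled to root-to-tip height 1, so all rates are per tree depth.
* **Predictors** are Brownian motion along branches (σ²_phylo = 1 per
  unit length) plus i.i.d. noise (σ²_ind = 0.25), affine-mapped to
  their output ranges; habitat cuts an independent Brownian latent
  into k equal-frequency levels. σ²_ind = 0.25 gives predictors a
  strong but imperfect phylogenetic structure — the regime in which
  correcting for relatedness matters.
* **Traits** come in two modes. Mode (a): direct Mk2 simulation with
  configured rates (default q01 = 1, q10 = 2 — asymmetric, a handful
  of expected changes across the tree, the regime where both
  parsimony and likelihood methods are informative). Mode (b): a
  liability threshold — liability = β·(standardised predictor) +
  Brownian component (σ² = 1) + Gaussian noise (σ_e = 0.5),
  thresholded at its realised median. The median threshold keeps
  prevalence near one half regardless of β, which keeps parsimony and
  RI statistics well conditioned; β = 1 by default for the linked
  traits (roughly, the predictor moves a species one residual
  standard deviation — a strong but not deterministic effect). The
  study-scale mix is 25 Mk2 + 12 height-linked + 12 elevation-linked
  traits.
* **Reproducibility.** Everything derives from one master seed;
  per-trait sub-seeds are spawned by trait index, so extending the
  trait list never perturbs existing traits. Ground truth (rates,
  betas, liabilities, internal node states) is stored with the data.

What the generator does **not** emulate: correlated blocks of
anatomical characters, habitat-specific trait syndromes, measurement
or coding error, and non-ultrametric (substitution-length) trees.
Passing tests on this generator show the machinery is correct and
calibrated under its assumptions; they do not show that any
particular empirical dataset satisfies those assumptions.

## Operating characteristics (the `experiments` module)

* With i.i.d. normal response and predictor (n = 40, 1999
  permutations, 1000 replicates) the single-trait test's size at
  α = 0.05 stays within the 99% binomial band of the nominal level.
* With a binary trait and a continuous predictor evolved
  *independently* on the same 39-tip trees (β = 0), the ahistorical
  test rejects far above nominal (phylogenetic pseudo-replication)
  while the PCo-corrected test returns to the nominal band — the
  core methodological point, demonstrated on ≥500 replicates.
* Pooled Mk2 fitting on 200 characters simulated with (0.5, 1.5) on a
  300-tip tree recovers both rates within 20% relative error, and
  among internal nodes reconstructed with PL ≥ 0.95 the true
  simulated state matches well above 90%.
* Characters simulated with low rates have a substantially higher
  mean RI than high-rate characters on the same tree.

These are exactly the quantities `scripts/acceptance.py` recomputes.

## Pipeline conventions

One master seed drives the whole run; each stage draws its seed from a
fixed spawn-key registry, and each single-trait test from a
(trait, predictor, mode) counter, so fused and stage-wise executions
agree exactly and reruns are byte-identical (the log deliberately
contains no wall-clock timestamps). All numeric artifacts are written
at full precision in JSON with rounded human-readable TSV twins. On
failure, completed stages remain on disk with a MANIFEST recording how
far the run got.

## Known limitations

* Multistate (>2 states) characters, rate variation among branches
  and stochastic character mapping are out of scope.
* The PCoA-eigenvector correction absorbs *linear* phylogenetic
  structure in trait space; strongly non-linear inertia may leak into
  the corrected tests.
* Mk2 rate estimates on single characters at 39 tips are noisy
  (boundary fits are flagged, not suppressed); pooled fits are the
  reliable mode at this scale.
* The permutation F-test treats 0/1 responses as numeric, as
  constrained-ordination practice does; it is a test of linear
  association, not a logistic model.
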