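# Methods

## Model

`fuzzygrade` treats molecular grading as two-class fuzzy classification.
Each tumor is described by per-probe membership degrees to a grade-1-like
(fMG1) and a grade-3-like (fMG3) class, learned from the histologic
grade-1/3 tumors of the cohort. Expression values are first min-max
standardized per probe into [0, 1] using bounds computed **on the training
samples only** — grade-2 and unknown-grade tumors never influence the
bounds, and their out-of-range values are clipped rather than extrapolated
so memberships stay well defined.

Two membership families are supported and compared automatically:

* **fuzzy binomial** `mu = rho^x (1-rho)^(1-x)`, `rho` = class mean of the
  standardized values. It is sharp when classes concentrate near 0 and 1
  but numerically fragile around 0.5, so `rho` and `x` are clamped to
  `[1e-6, 1 - 1e-6]` before the power form (evaluated in log space).
* **Gaussian** `mu = exp(-(x-mu_c)^2 / 2 sigma_c^2)`, with the class mean
  as center and the class SD (ddof = 1) as spread, floored at 0.01 on the
  unit-interval scale to prevent degenerate spikes on near-constant probes.

Per-sample memberships are aggregated per class with a mixed connective,
`GAD = alpha * T + (1-alpha) * S`, where `(T, S)` is min/max by default
(`prodsum` gives product / probabilistic sum). The exigency `alpha`
interpolates between demanding that *every* probe fit the class profile
(`alpha = 1`) and rewarding the single best-fitting probe (`alpha = 0`).
The molecular grade score `s = GAD3 / (GAD1 + GAD3)` normalizes the two
adequacies so they are displayed as complementary membership degrees;
`s >= 0.5` calls fMG3 (boundary inclusive) and `s` in the inclusive band
[0.48, 0.52] is flagged equivocal. A non-informative class (constant MAD
0.5) can be enabled to mark low-confidence calls, but is off by default.

## Feature weighting and signature sizing

MEMBAS scores each probe by its membership margin (membership to the
sample's own class minus membership to the other class) summed over
training samples. The weights maximize `w . m` subject to unit L2 norm and
non-negativity, giving the closed form `w ∝ max(m, 0)`; an all-non-positive
margin vector yields zero weights with a warning. Ties in the descending
ranking are broken by ascending probe identifier for reproducibility.
Margins are computed on the same samples used to fit the prototypes; this
global, resubstitution-style ranking is the default, and a per-fold
re-ranking mode (`rerank_per_fold=True`) is available when an unbiased
error estimate matters more than speed — under label permutation only the
per-fold mode recovers the chance-level baseline, which is how the two
modes are tested.

Signature sizes are evaluated by leave-one-out cross-validation along the
ranking. For every held-out sample the bounds and prototypes are re-fitted
from scratch on the remainder (verified fold-by-fold against a brute-force
refit in the tests), and the LOOCV decision for every candidate size k is
obtained in a single pass via prefix aggregation of the ranked MADs, making
the exact curve O(n · p · |alpha grid|). The exigency is grid-searched in
{0.5, 0.6, …, 1.0} per candidate size, keeping the value minimizing the
LOOCV global error (ties to the larger, stricter value); this treats alpha
as a classifier hyperparameter estimated by the same cross-validation that
sizes the signature. The chosen size is the smallest k whose sensitivity is
maximal among sizes with specificity ≥ `min_specificity` (default 0.67, the
weakest specificity still considered acceptable for a grading signature;
sensitivity is privileged because missing a high-risk tumor is the costlier
error). If no size reaches the floor the best-sensitivity size is used with
a warning. The final model is refitted on the full training set at that k.

`select_signature` runs the search over both membership families and, when
ER status is available, both ER stratification modes (all training tumors
vs ER-positive only — ER-negative tumors are enriched for high grade and
can bias the profiles), keeping the combination with the lowest LOOCV error
(ties to higher sensitivity). The deployment set is never ER-filtered.
Default candidate sizes are every k up to 200 and ~20 log-spaced values up
to the full probe count.

## Cross-platform transfer

To port a signature to a platform with several probes per gene, candidate
probes for each signature gene are ranked by MEMBAS weight on the new
cohort's grade-1/3 samples and the best probe per gene is retained (at
least 80% of genes must be covered; uncovered genes are dropped with a
warning). Prototypes and bounds are re-fitted on the new cohort with the
adapted probe list, keeping the original family, connective and exigency.

## Synthetic cohorts

The generator emulates log2-intensity microarray data: per-probe baselines
Uniform(6, 12), within-class Gaussian noise (SD 1.0), and a minority of
informative probes shifted upward by `effect` SD units (default 2.0) in the
grade-3 archetype. Defaults are 60 grade-1, 60 grade-3 and 60 grade-2
samples with 20 informative among 1000 probes. Grade-2 samples draw a
latent archetype (grade-3 with probability `grade2_mix`, default 0.5), and
10% of them are instead placed midway between the archetype means to
emulate genuinely intermediate profiles — this default sits inside the
single-digit-to-~30% equivocal-rate range such grading methods report on
real cohorts. ER status is an independent Bernoulli(0.7) label. The
two-platform generator re-measures the same samples with k probes per gene,
each an affine-distorted replicate with a per-probe jitter SD drawn from
[0, 0.5 SD].

What the generator does **not** emulate: probe-level cross-hybridization,
spatial/dye artifacts, batch effects, correlated gene modules, class
imbalance between cohorts, and ER-grade association. Passing tests
therefore demonstrate the correctness and internal calibration of the
pipeline, not its clinical accuracy on real tumors.

## Numerical and design notes

* Degenerate probes (constant on training data) standardize to 0.5 —
  non-informative for every class — and are logged.
* Missing entries are excluded from bound/prototype estimation and from
  aggregation (present-probe aggregation); classification refuses a sample
  missing more than 20% of signature probes (configurable).
* Displayed rates use half-up integer percent rounding; raw fractions are
  retained in all outputs.
* LOOCV requires at least two samples per class in every fold's remainder;
  cohort splitting requires at least five per training class.
* Determinism: same inputs and seeds reproduce traces and cohorts
  bit-for-bit; classification of a frozen model is deterministic.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the generator at its default
conditions; aggregate checks use 20–50 seeded cohorts per quantity and the
brute-force LOOCV oracle runs on a 40-probe subset, sizes at which the
whole suite completes in well under a minute while keeping the statistical
assertions (3-SE bands, ≥90%-of-seeds rates) meaningful.

## Known limitations

* The global MEMBAS ranking is mildly optimistic at small k (selection
  bias); the per-fold mode removes it at O(n) extra cost per fold.
* Only two-class grading is implemented; multi-class margins and the
  unsupervised/online LAMDA variants are out of scope.
* The reference-probe selector ranks candidates by expression stability
  (ascending variance) only; a correlation-based criterion is not
  implemented.
* Survival analysis is deliberately excluded: calls.tsv is designed to feed
  external survival tools.
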