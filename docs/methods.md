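# Methods

`symptomnet` implements the standard network-psychometrics workflow for
two co-administered ordinal symptom scales — here the 7-item anxiety
screener (GAD-7) and the 10-item depression screener (CES-D-10), both
coded 0–3 — from raw survey roster to a stability-assessed
partial-correlation network. This note documents the models, the
defaults and the numerical choices, and what the synthetic validation
does and does not establish.

## Cohort screening

The analytic sample is assembled by a staged cascade over respondents
with the living-alone code:

1. records missing age or sex, or with more than one third of the 17
   scale items missing, are removed;
2. among survivors, records with any missing GAD-7 item are removed;
3. among the remainder, records with any missing CES-D item are removed.

A record is attributed to the *first* stage that rejects it, so stage
counts are disjoint and conservation (`retained + excluded = input`)
holds exactly. The one-third rule is evaluated over all 17 items
jointly with a strict inequality (6 or more missing items fail; 5 do
not). Raw-file missingness sentinels (blanks, `NA`, `.`, out-of-range
codes such as 8/9) all map to missing; survey export dialects vary too
much to privilege one convention. No imputation is performed anywhere.

Scale totals are plain sums; screening flags use the standard cutoffs
(GAD-7 ≥ 5, CES-D-10 ≥ 10), and prevalences are reported as computed
percentages of the retained sample — the package never rounds a count
to force agreement with an externally printed percentage.

## Association matrix

Associations are pairwise Spearman rank correlations with average
ranks, appropriate for heavily tied 4-category items, and invariant to
monotone recoding. A pairwise rank-correlation matrix need not be
positive semidefinite; before entering the estimator it is repaired by
eigenvalue clipping at zero followed by rescaling to unit diagonal. A
matrix that is already PSD is passed through unchanged. Polychoric
correlations are deliberately out of scope: the estimator consumes the
observed-rank association, and the attenuation this induces relative
to the latent scale is discussed under *Calibration* below.

## Network estimation

The network is a Gaussian graphical model: edge weights are partial
correlations obtained from an L1-penalized precision estimate,

    maximize  log det Θ − tr(SΘ) − λ Σ_{i≠j} |θ_ij|,
    w_ij = −θ_ij / √(θ_ii θ_jj).

The penalty excludes the diagonal, which preserves the exact
empty-network threshold: for λ ≥ max_{i≠j} |s_ij| the solution is
diagonal. The solver is the graphical lasso (block coordinate descent
over the dual) as implemented in scikit-learn; at λ = 0 the precision
is the direct (pseudo-)inverse. The default dual-gap tolerance is
1e-4 with 500 sweeps: tighter tolerances are unreachable on
rank-correlation inputs, whose dual gap stalls around 1e-5 at this
dimension. When a fit stalls above tolerance the solver retries once
at 25× the tolerance (with a warning); a λ that still fails —
typically the smallest grid points on near-singular input — is
excluded from selection, along with every smaller λ, rather than
aborting the analysis.

λ is chosen on a log-spaced grid of 100 points from λ_max down to
0.01·λ_max by minimizing the Extended Bayesian Information Criterion
in the Foygel–Drton form

    EBIC = −2L + E log n + 4 γ E log p,   L = (n/2)(log det Θ − tr(SΘ)),

with E the number of nonzero undirected edges and γ = 0.5 by default.
Two selection modes exist:

* **`direct_ebic`** (default): whole-sample fit, whole-sample EBIC.
  This is the convention of the R network-psychometrics stack
  (qgraph's `EBICglasso`) and the field's standard.
* **`cv_ebic`**: rows are split into seeded folds; each λ is scored by
  the mean EBIC of training-fold fits evaluated against held-out-fold
  Spearman matrices at the held-out sample size.

The cross-validated variant is exposed because selection-by-held-out
score is sometimes described in applied reports, but it is *not* the
default: applying the EBIC complexity terms at the held-out sample
size on top of an out-of-sample likelihood penalizes model complexity
twice, and in simulation the procedure collapses to the empty network
even when the data carry a strong planted structure. Users wanting a
held-out criterion should understand it as a conservative
cross-check, not a replacement.

A sensitivity helper re-runs selection at γ ∈ {0.1, 0.5, 0.9} and
reports pairwise edge-set Jaccard overlap and weight correlations;
edge counts are non-increasing in γ on all fixtures tested.
"Nonzero" means |w| above 1e-10; the solver's numerical zeros are
truncated.

## Centrality

Expected influence (EI) defaults to the absolute variant
EI_i = Σ_j |w_ij| — the definition used in the reports this pipeline
mirrors — with the signed one-step variant exposed; the two coincide
on all-positive networks, which these scales typically produce.
Bridge expected influence (BEI) is the signed sum of a node's edges
into the other community. Raw values are primary (z-scores are
optional extra columns); EI ranks run over all nodes, BEI ranks
within community, and ties break lexicographically by node label so
output is deterministic.

## Bootstrap accuracy and stability

* **Edge CIs**: nonparametric row resampling with replacement; the
  entire estimator, penalty selection included, is re-run per
  resample; CIs are percentile intervals (default 95%, B = 1000).
  Resamples that degenerate (a zero-variance column) are redrawn and
  counted.
* **Case-dropping bootstrap**: for each drop proportion d in
  0.10–0.75 (step 0.05), B subsets of size round((1−d)·n) are drawn
  without replacement; subset EI/BEI vectors are Pearson-correlated
  with the full-sample vectors. The CS coefficient is the largest d
  at which the correlation is ≥ 0.7 with empirical probability
  ≥ 0.95. An undefined correlation (e.g. an empty subset network)
  counts as a failure. B draws are spent per proportion, so the grid
  costs 14·B estimations; reduced B is advisable for exploration and
  the outputs annotate the count used.
* **Difference tests**: an edge pair (or node pair, for EI/BEI
  recomputed per draw) differs when the percentile interval of the
  bootstrap differences excludes zero. No multiplicity correction is
  applied; these are exploratory displays, as in the protocol this
  follows.

CS values are annotated against the conventional 0.25 (minimum) and
0.50 (robust) interpretation bands but never enforced.

## Synthetic data generator

The generator plants a known sparse GGM over two communities (7 + 10
nodes by default): positive-dominant chains within each community plus
random extra edges at a configurable density, and a set of
cross-community bridge edges. The default bridge set places four
bridges — strongest between the nervousness item and the sleep item
(0.34), then worry–effort (0.28), relaxing–loneliness (0.13) and
irritability–blue (0.12) — mirroring the bridge structure reported
for this symptom pair in older adults living alone. The precision
matrix is built with unit diagonal, so requested partial correlations
are planted exactly; an infeasible (non-PD) request raises rather
than being silently rescaled.

Ordinal responses are latent-Gaussian copula draws: multivariate
normal with the standardized inverse precision as correlation,
discretized per item at three fixed cut points. Default cuts are
derived from target item means (anxiety items 0.15–0.34, depression
items 0.79–1.90 on the 0–3 scale) by assuming geometric-decay
category probabilities, which reproduces the right-skew typical of
community screening data. A missingness injector plants an exact
number of failures per screening stage (demographic/incompleteness,
anxiety block, depression block) so flow counts can be tested
exactly; demographics (age ≈ N(84, 9.4²) truncated at 65, 38% male,
mostly rural/town residence) resemble a community sample of older
adults living alone.

What the generator does **not** emulate: survey design effects and
weights, item-level measurement error beyond the copula, informative
(non-random) missingness, and any dependence of symptoms on
demographics. Passing recovery tests therefore demonstrate that the
estimation chain recovers a known sparse ordinal-latent structure at
these sample sizes — not that any real dataset satisfies the model.

## Calibration: what the bootstrap CIs do and do not cover

Two systematic effects separate an estimated edge weight from the
latent partial correlation planted by the generator:

1. **Ordinal attenuation.** Spearman correlations of 4-category
   discretized variables understate the latent correlations; for the
   default small-network fixture the λ→0 probability limit of the
   planted 0.30 bridge is ≈ 0.26.
2. **Lasso shrinkage.** At EBIC-selected λ (≈ 0.02–0.04 at n = 2000)
   retained edges are biased toward zero by roughly the penalty size.

Percentile bootstrap intervals re-estimate the same penalized,
attenuated quantity in every resample, so they quantify *sampling
variability around the estimate* — they are not confidence intervals
for the latent weight, and in simulation their coverage of the
planted latent value is far below nominal (the acceptance script
reports the measured value; with interval half-widths ≈ 0.04 and a
combined bias of similar size, coverage lands near 10–30%). This is
a property of the estimator class, not an implementation defect: the
bootstrap protocol this package mirrors carries the same caveat in
its own documentation. The acceptance script therefore reports,
alongside the latent-value coverage, the coverage of the estimator's
own large-n limit and the null-data check (≥90% of CIs containing
zero on independent columns), which are the calibration properties
the percentile bootstrap can honestly claim.

## Layout and reporting

Node positions come from a seeded Fruchterman–Reingold iteration
(networkx's spring layout) with |w|-weighted attraction, rescaled to
the unit box; identical seed and weights give identical coordinates.
Edges render blue for positive and red for negative weights with
thickness and saturation linear in |w| relative to the largest
|w|. Every figure ships with node/edge sidecar tables that
reconstruct the styled network exactly, and the summary table (one
row per symptom: name, abbreviation, mean, SD, EI, BEI; anxiety items
first) rounds to two decimals in its display form.

## Pipeline determinism and problem sizes

One global seed deterministically derives per-stage seeds
(`SeedSequence`); the manifest records them and the SHA-256 of every
artifact, so a rerun with the same config is verifiable bit-for-bit.
Every analysis constant (cutoffs 5 and 10, γ = 0.5, 10 folds,
B = 1000, CI 0.95, drop grid) lives in the run config, not in code.

Validation studies use deliberately modest sizes chosen to make their
statistical point at desk scale: parameter recovery averages 20
generator seeds at n = 2000 on the default 17-node network; CI
calibration uses a 3+3-node planted network (one 0.3 bridge),
100 outer replicates × 200 inner resamples; the duplicated-rows
stability fixture duplicates 2000 rows of a 3+3 network with two
strong bridges (0.30/0.22) — a small node set with only strong
bridges is what makes "subsampling barely perturbs the estimates"
actually true, since on wide networks borderline cross-community
edges flicker across subsamples and dominate the bridge-centrality
vector; case-dropping fixtures use B = 25–50 per drop proportion. The methods' conclusions do not
change at larger sizes — recovery and stability improve monotonically
with n on all fixtures tested (one inversion tolerated at small n).

## Known limitations

* Spearman input attenuates latent associations of coarsely
  discretized items; polychoric input is out of scope.
* Percentile edge CIs describe estimate variability, not latent-value
  coverage (see *Calibration*).
* Difference tests are uncorrected for multiplicity and exploratory.
* Communities are fixed by instrument membership; no community
  detection is attempted.
* The cross-validated EBIC mode is a conservative cross-check, not a
  calibrated selector.
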