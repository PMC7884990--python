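# Methods

This note documents the models, parameter choices, and numerical
conventions behind `sparenet`, and what the synthetic validation does
and does not establish about real data.

## Normative edge z-scoring

For each unordered node pair (i, j) the control reference stores the
presence count `c_ij` (controls with streamlines on the edge) and the
sample mean and SD (n−1 denominator) of gFA *over the controls that
possess the edge*. Absent edges are not zero-imputed: deterministic
tractography produces sparse networks in which a missing edge is more
plausibly a tracking failure than a true zero, and standardizing against
a zero-inflated distribution would conflate the two. For the same reason
a patient edge is z-scored only when the patient possesses it — absence
in the patient is not treated as abnormality.

An edge is assessable when the patient has it, at least `min_controls`
controls have it (default 10, roughly 35% of a 29-control cohort), and
the control SD is positive. A zero control SD (all controls identical to
machine precision) would produce infinite z-scores, so such edges are
marked invalid instead. The z-scoring of a held-out control against the
remaining controls yields edge z-scores with mean ≈ 0 and SD ≈ 1, which
the test suite checks.

## Virtual resection and the spared network

Surgery can only remove streamlines, so the surgically spared network is
the presurgery z-network restricted to edges not named in the
surgery-affected set. The affected set is an *input* (two-column edge
list); deriving it from imaging (streamline/resection-mask intersection)
is out of scope. Two conventions matter downstream:

- **Presurgical degrees are frozen.** Node degree `k_i` is the count of
  valid presurgery edges and is carried unchanged into the spared
  network, so node abnormality stays a fraction of the originally
  assessable links and spared flags are a subset of presurgery flags.
- **Disconnected nodes are kept.** A node whose every edge is removed
  keeps `p_i = 0` rather than being dropped, keeping loads comparable
  across patients.

## Node abnormality and the threshold grid

A link is abnormal when `|z| ≥ τ_z`. The absolute value is the default
because deviation from normality is two-sided; a configuration switch
(`abs` / `negative-only` / `positive-only`) restricts to reduced or
increased anisotropy. Both threshold comparisons are inclusive
(`≥ τ_z`, `≥ τ_p`). The default grid runs τ_z = 2.1…4.5 in steps of 0.1
and τ_p = 1%…50% in steps of 1%; grid values are generated by integer
indexing (21…45 × 0.1) to avoid floating-point accumulation. The
abnormality load — the abnormal-node count — is non-increasing along
both grid axes, and the vectorized grid computation is tested
cell-by-cell against a loop-based enumeration oracle.

Threshold selection for the classifier maximizes the rank-based AUC of
load versus outcome across training patients, with ties broken toward
the lowest τ_z, then the lowest τ_p — a deterministic convention that
favors the least aggressive threshold among equally discriminative ones.

## Regional summaries

Nodes are relabeled ipsilateral/contralateral to each patient's surgery
and grouped into six areas per side (temporal, subcortical, parietal,
occipital, frontal, cingulate). Per (side × area) cell the package
reports group-mean abnormal proportions for the presurgery and spared
networks, their drop, and a paired t-test across patients on the
per-patient proportions. The paired-t construction is an interpretation:
group-level t statistics on proportion drops admit several designs, and
a paired test across patients is the one consistent with reporting a
mean drop with a CI. Standard errors are across patients. P-values are
left uncorrected so callers can apply BH-FDR over whichever family of
cells they report.

## Statistical toolkit

All tests used by the analysis are implemented from first principles so
their behavior is oracle-verifiable; scipy/statsmodels equivalents are
used as independent cross-checks in the test suite, never as the
implementation.

- **Exact rank-sum.** One-tailed Wilcoxon rank-sum with mid-ranks for
  ties. For combined n up to a cap (default 25) the null distribution is
  computed exactly by dynamic programming over doubled ranks, which is
  equivalent to full enumeration of all C(N, n1) rank assignments.
  Beyond the cap a tie-corrected normal approximation with continuity
  correction is used and flagged in the method descriptor. The direction
  of the one-tailed alternative is always supplied by the caller.
- **BCa bootstrap.** Bias correction ẑ₀ from the fraction of resample
  statistics below the observed value (ties counted half), acceleration
  from leave-one-out jackknife skewness, adjusted percentiles applied to
  the resample distribution with linear-interpolation quantiles. A
  degenerate resample distribution falls back to a point interval with a
  warning. Statistics that accept an `axis` argument (like `np.median`)
  are evaluated in a single vectorized call.
- **BH-FDR.** Step-up procedure with adjusted p-values by reverse
  cumulative minimum.
- **Spearman.** Mid-rank Pearson correlation with a t-approximation
  p-value (flagged as an approximation in the descriptor).
- **Robust slope + permutation test.** The regression variant behind the
  published slope test is under-determined, so a bisquare (Tukey
  biweight, c = 4.685, MAD scale) IRLS straight-line fit was chosen; the
  permutation p-value is primary, so the variant mainly affects power.
  The permutation p uses the add-one convention
  (1 + #{|slope*| ≥ |slope|}) / (n_perm + 1), which cannot return 0.
  Note one consequence: even for perfectly collinear data the p-value
  can exceed its nominal minimum, because the biweight can fit a
  near-reversed permutation steeply by downweighting discordant points.
- **Paired t.** Closed form with a t-based CI on the mean difference.

## Synthetic cohort generator

The generator emulates the study design end to end: a shared scaffold
topology (an atlas-like constraint) with per-subject edge dropout,
per-edge Gaussian gFA populations truncated to (0, 1), log-normal
streamline counts (topology only — they carry no abnormality signal),
planted abnormal subnetworks, resections, 13 clinical covariates, and
outcome labels.

**Planted abnormalities.** Each patient receives `planted_nodes_per_
patient` (default 8) abnormal nodes; every scaffold edge incident to a
planted node has its population gFA mean shifted by
`planted_sign · planted_effect · σ_ij` (default −4σ, reduced anisotropy
as in the epilepsy literature; the sign is configurable). A uniformly
drawn fraction of each patient's planted nodes lies inside the
to-be-resected ipsilateral temporal area; the rest are placed
preferentially ipsilaterally. The across-patient spread in how much
planted abnormality survives surgery is what drives outcomes.

**Scaffold density.** The default scaffold is dense
(`scaffold_density = 0.95`, `edge_dropout = 0.08`), giving assessable
degrees near 100. This is a deliberate design requirement, not a claim
about tractography sparsity: a non-planted node's expected abnormal
fraction is ≈ (8/113) × flag-probability ≈ 6–7%, just below the 10%
node cutoff, and only a large assessable degree keeps the binomial
noise in that fraction from pushing neighbor nodes over the cutoff.
With a sparse scaffold (density ≈ 0.25, degree ≈ 25) neighbor nodes sit
on the cutoff boundary and planted abnormalities no longer localize —
the planted-recovery property (recall ≥ 0.9, leakage ≤ 5% at
(2.8, 10%)) that the tests assert would be meaningless. Real cohorts
achieve the same localization through degrees that are large relative
to the abnormal subnetwork.

**Outcomes.** ILAE class at year 1 follows an ordered-logit model:
latent score = intercept + slope × true spared load + coefficients on
standardized clinical covariates + standard-logistic noise, cut at
ordinal points. Defaults (intercept −6.0, slope 1.2, cutpoints 0.2,
1.4, 2.6, 3.8) were calibrated by simulation to emulate a cohort of
roughly 33 ILAE 1, 7 ILAE 2, and 11 ILAE 3–5 patients out of 51. Yearly
relapse for patients at ILAE 1–2 is Bernoulli with hazard
logistic(−4.5 + 0.75 × true spared load); these values reproduce
year-5 relapse/no-relapse groups of roughly 13 vs 14 and keep relapse
load-driven rather than base-rate-driven. Follow-up horizons are drawn
per patient (multinomial over 2–5 years); unobserved years are censored
(missing), and relapse labels exist only for patients at ILAE 1–2.

**Ground truth.** For each patient the generator records planted nodes
and edges, the affected set, and "true" pre/spared abnormality loads —
the nodes whose planted-edge fraction of present-degree reaches 10%,
recomputable from the recorded sets alone. On noiseless instances this
equals the pipeline's load at the generating thresholds.

**What the synthetic validation does not show.** The generator has no
spatial autocorrelation, no age/sex structure in the networks, no
scanner effects, and abnormality confined to an exact node subset; real
abnormality is diffuse and graded. Passing tests establish that the
pipeline recovers what it is pointed at under its own assumptions, not
that those effect sizes occur in patients.

## Prediction pipeline

Outer leave-one-out runs over ILAE 1 and ILAE 3–5 patients only. Per
fold, using training patients only: (τ_z, τ_p) selected per network
kind; features standardized; the SVM regularization parameter C chosen
from a log-spaced grid (10⁻³…10³, 13 points) by stratified 5-fold inner
CV on validation AUC (leave-one-out inner CV is available by
configuration); a linear SVC fit with inverse-class-frequency weights
(the cohort is ≈ 33 vs 11); and a sigmoid (Platt) calibration of
decision values fit on the training fold. The held-out patient's
calibrated probability of the not-seizure-free class is its predicted
relapse likelihood. ILAE 2 patients never enter training and are scored
by averaging all outer-fold models' probabilities.

Feature importances are |w| rescaled to [0, 1] per fold; elimination
drops the feature with the smallest mean importance across outer folds
(ties by feature order), re-running the full outer loop at each of the
15 → 1 steps. Reported per-step importances are the cross-fold means
renormalized to [0, 1]. Classification metrics use the 0.5 probability
threshold; sensitivity is recall of the not-seizure-free class. Because
each held-out patient is scored by a different fold model, pooled LOO
probabilities can rank imperfectly even on separable data —
a property of pooled cross-validated scores, not a defect of the fit.

## Problem sizes and numerical conventions

Simulation-based checks run at sizes chosen to balance statistical
resolution against desk-scale runtimes: BCa coverage uses 500 samples
of n = 30 at 2,000 resamples; FDR control uses 100 repeats of a
1,000-test mixture; permutation-test uniformity uses 200 datasets at
200 permutations; the label-shuffle leakage null uses 20 repeats on an
18-patient cohort with a reduced C grid and 2-fold inner CV (leakage,
if present, does not depend on grid resolution). The effect-recovery
run uses the full default configuration on a 50-patient cohort. All
entry points with randomness take an explicit seed; identical seeds
give byte-identical outputs, and fold-level seeds are derived from the
master seed via `SeedSequence`.
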