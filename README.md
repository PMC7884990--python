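# sparenet

Structural brain-network abnormality mapping and seizure-outcome
prediction for epilepsy surgery cohorts.

## The problem

About a third of patients with drug-resistant temporal lobe epilepsy
(TLE) continue to have seizures after anterior temporal lobe resection
(ATLR). One hypothesized driver is the epileptogenic network that the
surgery leaves behind: white-matter connections whose microstructure
deviates from normal and whose streamlines avoid the resection cavity.
`sparenet` implements an analysis of exactly that quantity, for
researchers working with diffusion-MRI connectomes (one mean-gFA and one
streamline-count matrix per subject, plus per-patient surgery-affected
edge lists):

1. **Normative z-scoring.** Each patient edge weight `w_ij` (mean
   generalized fractional anisotropy, gFA) is standardized against the
   distribution of the same connection in a control cohort:
   `z_ij = (w_ij − μ_ij) / σ_ij`, where `μ_ij`, `σ_ij` are the mean and
   SD over the controls that possess the edge. Edges present in fewer
   than `min_controls` controls (default 10) are not assessed.
2. **Virtual resection.** Removing the surgery-affected edges from the
   presurgery z-network yields the *surgically spared* network — the
   abnormality expected to remain after the operation.
3. **Node abnormality load.** A link is abnormal when `|z| ≥ τ_z`; node
   `i` is abnormal when at least `τ_p` percent of its presurgical-degree
   links are abnormal (`p_i = 100·a_i/k_i`). The *abnormality load* is
   the abnormal-node count, evaluated over a grid of 25 × 50 threshold
   pairs (τ_z from 2.1 to 4.5 by 0.1, τ_p from 1% to 50% by 1%).
4. **Regional surgery effect.** Nodes are relabeled ipsi/contralateral
   to surgery and grouped into six areas per side; per-area abnormal
   proportions are compared between presurgery and spared networks
   (paired t across patients, BH-FDR correctable).
5. **Outcome prediction.** A linear SVM combines 13 clinical covariates
   with the presurgery and spared abnormality loads to separate
   seizure-free (ILAE 1) from not-seizure-free (ILAE 3–5) patients at
   year 1, inside nested leave-one-out cross-validation: threshold
   pairs, feature scaling, the regularization parameter, and the
   sigmoid probability calibration are all re-derived per fold.
   Recursive feature elimination sweeps 15 → 1 features. Calibrated
   probabilities of the not-seizure-free class — the predicted
   *likelihood of seizure relapse* — are tested against the year-1 ILAE
   class (Spearman, robust-slope permutation test) and against actual
   relapse in follow-up years 2–5 (one-tailed exact rank-sum, Cohen's
   d, BCa bootstrap CIs).

Real MRI-derived cohorts are rarely shareable, so the package ships a
synthetic-cohort generator (`sparenet.synthetic`) that plants abnormal
subnetworks with known ground truth, applies resections, and draws ILAE
outcomes and relapse events from the abnormality load that survives
surgery. Every pipeline stage is validated against that ground truth.

## Worked example

```python
import sparenet as sn

cfg = sn.GeneratorConfig(n_patients=50, seed=1)
cohort = sn.generate_cohort(cfg)

ref = sn.build_reference(cohort.controls)
zn = sn.z_score_network(cohort.patients[0], ref, min_controls=10)
spared = sn.apply_resection(zn, cohort.effects[0])

profile = sn.node_abnormality_profile(spared, tau_z=2.8)
load, nodes = sn.abnormality_load(profile, tau_p=10.0)
print(f"patient {cohort.patients[0].subject_id}: "
      f"{zn.edge_count()} z-scored edges, {spared.edge_count()} spared, "
      f"spared abnormality load = {load}")
print("abnormal nodes:", [cohort.nodes['label'][i] for i in nodes])
print("true planted nodes:", cohort.truths[0].planted_nodes)
```

prints

```
patient patient001: 5620 z-scored edges, 4171 spared, spared abnormality load = 2
abnormal nodes: ['L044', 'R028']
true planted nodes: ['L044', 'R002', 'R005', 'R006', 'R009', 'R010', 'R011', 'R028']
```

This patient had 8 planted abnormal nodes; 6 of them sat in or near the
resected ipsilateral temporal area, so only 2 abnormal nodes survive in
the spared network — the quantity the outcome model feeds on.

The prediction stage follows a Model/Results layout:

```python
result = sn.run_pipeline(cohort, sn.PipelineConfig(seed=1))
print(result.prediction.summary())        # per-step AUC/accuracy + importances
probs = result.relapse["probabilities"]   # spared-load-only relapse likelihoods
```

The full pipeline is also available from the shell:

```bash
sparenet simulate --out cohort/ --seed 1
sparenet run --cohort cohort/ --out results/ --seed 1
sparenet report --results results/
```

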