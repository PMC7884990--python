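"""Seizure-outcome prediction from clinical covariates and abnormality load.

A linear maximum-margin classifier separates seizure-free (ILAE 1) from
not-seizure-free (ILAE 3-5) patients at year 1, inside a nested
leave-one-out scheme: for every held-out patient, the discriminatory
(tau_z, tau_p) threshold pairs, the feature scaling, the regularization
parameter (inner stratified CV) and the probability calibration are all
re-derived from the remaining patients only. Recursive feature
elimination sweeps from the full feature set down to a single feature,
dropping the feature with the smallest mean absolute weight at each step.
Calibrated probabilities of the not-seizure-free class are interpreted as
the predicted likelihood of seizure relapse; ILAE 2 patients are never
trained on and are scored by averaging the outer-fold models.

The module follows a Model/Results layout: build a
:class:`RelapseLikelihoodModel` from a feature table, call ``fit()``, and
inspect the returned :class:`RelapseLikelihoodResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .abnormality import AbnormalityGrid, pairwise_auc, select_threshold_pair
from .stats import (
    StatResult,
    bootstrap_ci_bca,
    cohen_d,
    permutation_slope_test,
    ranksum_exact,
    spearman_rho,
)

LOAD_FEATURES = ("presurgery_load", "spared_load")


@dataclass
class PredictConfig:
    """Hyperparameters of the nested-LOO prediction pipeline."""

    c_grid: np.ndarray = field(default_factory=lambda: np.logspace(-3, 3, 13))
    inner_cv: int | str = 5          # stratified k-fold, or "loo"
    class_weight: str | None = "balanced"
    probability_threshold: float = 0.5
    seed: int = 0


@dataclass
class FeatureTable:
    """Per-patient features and outcome labels for the classifier.

    ``clinical`` holds the clinical covariates (one row per patient);
    ``pre_grids`` / ``spared_grids`` hold each patient's abnormality-load
    grids, from which the two load features are extracted at the
    fold-selected thresholds. ``ilae`` is the year-1 ILAE class (1-5) and
    ``relapse`` the per-year relapse indicators (NaN = censored or not
    applicable).
    """

    clinical: pd.DataFrame
    pre_grids: list
    spared_grids: list
    ilae: np.ndarray
    relapse: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ilae = np.asarray(self.ilae, dtype=int)
        n = len(self.clinical)
        if not (len(self.pre_grids) == len(self.spared_grids) == self.ilae.size == n):
            raise ValueError("feature table components must have one entry per patient")

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    @property
    def feature_names(self) -> list[str]:
        return list(self.clinical.columns) + list(LOAD_FEATURES)

    @property
    def labeled_mask(self) -> np.ndarray:
        """Patients entering training: ILAE 1 (negative) or ILAE 3-5 (positive)."""
        return (self.ilae == 1) | (self.ilae >= 3)

    @property
    def labels(self) -> np.ndarray:
        """Binary not-seizure-free label for labeled patients (ILAE 3-5 = 1)."""
        return (self.ilae[self.labeled_mask] >= 3).astype(int)


@dataclass
class FoldModel:
    """Everything learned from one outer-fold training set."""

    feature_names: list
    thresholds: dict              # kind -> (tau_z, tau_p, train AUC)
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    C: float
    w: np.ndarray
    intercept: float
    calib_slope: float
    calib_intercept: float
    importances: np.ndarray       # |w| rescaled to [0, 1]

    def decision(self, X: np.ndarray) -> np.ndarray:
        Xs = (X - self.scale_mean) / self.scale_sd
        return Xs @ self.w + self.intercept

    def probability(self, X: np.ndarray) -> np.ndarray:
        return expit(self.calib_slope * self.decision(X) + self.calib_intercept)


def classification_metrics(
    probabilities, labels, threshold: float = 0.5
) -> dict:
    """AUC (rank-based, ties = 1/2), accuracy, sensitivity, specificity.

    Sensitivity is recall of the not-seizure-free (positive) class,
    specificity recall of the seizure-free class, both at the given
    probability threshold.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("metrics require both classes present")
    pred = (p >= threshold).astype(int)
    pos, neg = y == 1, y == 0
    return {
        "auc": pairwise_auc(p, y == 1),
        "accuracy": float((pred == y).mean()),
        "sensitivity": float((pred[pos] == 1).mean()),
        "specificity": float((pred[neg] == 0).mean()),
    }


# ---------------------------------------------------------------------------
# Model


class RelapseLikelihoodModel:
    """Nested leave-one-out outcome classifier with feature elimination.

    Parameters
    ----------
    table : FeatureTable
    config : PredictConfig, optional
    """

    def __init__(self, table: FeatureTable, config: PredictConfig | None = None):
        self.table = table
        self.config = config or PredictConfig()
        labels = table.labels
        if labels.sum() < 2 or (1 - labels).sum() < 2:
            raise ValueError("need at least 2 patients per outcome class")

    @classmethod
    def from_cohort(cls, clinical, pre_grids, spared_grids, ilae, relapse=None,
                    config=None):
        return cls(
            FeatureTable(
                clinical=clinical,
                pre_grids=pre_grids,
                spared_grids=spared_grids,
                ilae=ilae,
                relapse=relapse,
            ),
            config,
        )

    # -- internals ----------------------------------------------------------

    def _fold_thresholds(self, train_global: np.ndarray) -> dict:
        """Discriminatory threshold pairs from training patients only."""
        t = self.table
        y_train = (t.ilae[train_global] >= 3).astype(int)
        out = {}
        for kind, grids in (("presurgery", t.pre_grids), ("spared", t.spared_grids)):
            sub = [grids[i] for i in train_global]
            out[kind] = select_threshold_pair(sub, y_train)
        return out

    def _design_matrix(self, thresholds: dict, feature_names: list) -> np.ndarray:
        """Feature matrix for all patients at the fold's thresholds."""
        t = self.table
        cols = []
        for name in feature_names:
            if name == "presurgery_load":
                tz, tp, _ = thresholds["presurgery"]
                cols.append([g.load_at(tz, tp) for g in t.pre_grids])
            elif name == "spared_load":
                tz, tp, _ = thresholds["spared"]
                cols.append([g.load_at(tz, tp) for g in t.spared_grids])
            else:
                cols.append(t.clinical[name].to_numpy(dtype=float))
        return np.column_stack(cols)

    def _select_C(self, X: np.ndarray, y: np.ndarray, seed: int) -> float:
        cfg = self.config
        min_class = min(int(y.sum()), int((1 - y).sum()))
        if cfg.inner_cv == "loo":
            splits = [(np.setdiff1d(np.arange(y.size), [i]), np.array([i]))
                      for i in range(y.size)]
        else:
            k = max(2, min(int(cfg.inner_cv), min_class))
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            splits = list(skf.split(X, y))
        scores = np.zeros(len(cfg.c_grid))
        for ci, C in enumerate(cfg.c_grid):
            fold_scores = []
            for tr, va in splits:
                if len(np.unique(y[tr])) < 2:
                    continue
                svc = SVC(kernel="linear", C=C, class_weight=cfg.class_weight)
                svc.fit(X[tr], y[tr])
                dec = svc.decision_function(X[va])
                if len(np.unique(y[va])) < 2:
                    # single-class validation split: score by margin agreement
                    fold_scores.append(float((np.sign(dec) == 2 * y[va] - 1).mean()))
                else:
                    fold_scores.append(pairwise_auc(dec, y[va] == 1))
            scores[ci] = np.mean(fold_scores) if fold_scores else 0.0
        return float(cfg.c_grid[int(np.argmax(scores))])

    def fold_train(
        self,
        train_global: np.ndarray,
        feature_names: list,
        seed: int,
        thresholds: dict | None = None,
    ) -> FoldModel:
        """Fit one outer-fold model from training patients only."""
        cfg = self.config
        t = self.table
        y = (t.ilae[train_global] >= 3).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training fold must contain both classes")
        if thresholds is None:
            thresholds = self._fold_thresholds(train_global)
        X_all = self._design_matrix(thresholds, feature_names)
        X = X_all[train_global]

        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - mean) / sd

        C = self._select_C(Xs, y, seed)
        svc = SVC(kernel="linear", C=C, class_weight=cfg.class_weight)
        svc.fit(Xs, y)
        w = svc.coef_.ravel()
        b = float(svc.intercept_[0])

        dec = Xs @ w + b
        calib = LogisticRegression(C=1e6, max_iter=1000)
        calib.fit(dec.reshape(-1, 1), y)
        a = float(calib.coef_[0, 0])
        c0 = float(calib.intercept_[0])

        absw = np.abs(w)
        imp = absw / absw.max() if absw.max() > 0 else absw
        return FoldModel(
            feature_names=list(feature_names),
            thresholds=thresholds,
            scale_mean=mean,
            scale_sd=sd,
            C=C,
            w=w,
            intercept=b,
            calib_slope=a,
            calib_intercept=c0,
            importances=imp,
        )

    # -- public API ---------------------------------------------------------

    def loo_probabilities(self, feature_names: list | None = None) -> np.ndarray:
        """Leave-one-out probabilities for all patients at a fixed feature set.

        Labeled patients get the probability from the fold that held them
        out; ILAE 2 patients get the average probability across all outer
        folds (they never enter training).
        """
        feature_names = feature_names or self.table.feature_names
        probs, _, _ = self._run_loo(feature_names)
        return probs

    def _run_loo(self, feature_names: list):
        t = self.table
        labeled = np.flatnonzero(t.labeled_mask)
        unlabeled = np.flatnonzero(~t.labeled_mask)
        seeds = _fold_seeds(self.config.seed, len(labeled))

        if not hasattr(self, "_threshold_cache"):
            self._threshold_cache = {}
        probs = np.full(t.n_patients, np.nan)
        unl_acc = np.zeros((len(labeled), len(unlabeled)))
        importances = np.zeros((len(labeled), len(feature_names)))
        for f, test_idx in enumerate(labeled):
            train_global = labeled[labeled != test_idx]
            assert test_idx not in train_global
            key = int(test_idx)
            if key not in self._threshold_cache:
                self._threshold_cache[key] = self._fold_thresholds(train_global)
            fm = self.fold_train(
                train_global, feature_names, seeds[f],
                thresholds=self._threshold_cache[key],
            )
            X_all = self._design_matrix(fm.thresholds, feature_names)
            probs[test_idx] = fm.probability(X_all[[test_idx]])[0]
            if len(unlabeled):
                unl_acc[f] = fm.probability(X_all[unlabeled])
            importances[f] = fm.importances
        if len(unlabeled):
            probs[unlabeled] = unl_acc.mean(axis=0)
        return probs, importances, labeled

    def fit(self, min_features: int = 1) -> "RelapseLikelihoodResults":
        """Run the full recursive-feature-elimination sweep.

        Starts from all available features and repeatedly removes the one
        with the smallest mean importance (mean |w| across outer folds,
        renormalized to [0, 1]; ties broken by feature order) until
        ``min_features`` remain. Returns a results object with per-step
        metrics, probabilities, and importance maps.
        """
        t = self.table
        all_names = t.feature_names
        current = list(all_names)
        y = t.labels
        labeled = np.flatnonzero(t.labeled_mask)

        steps = []
        prob_steps = np.full((t.n_patients, len(current) - min_features + 1), np.nan)
        imp_map = pd.DataFrame(
            np.nan, index=range(len(current) - min_features + 1), columns=all_names
        )
        eliminated = []
        step = 0
        while len(current) >= max(min_features, 1):
            probs, importances, _ = self._run_loo(current)
            mean_imp = importances.mean(axis=0)
            top = mean_imp.max()
            norm_imp = mean_imp / top if top > 0 else mean_imp
            metrics = classification_metrics(
                probs[labeled], y, self.config.probability_threshold
            )
            steps.append({"n_features": len(current), **metrics})
            prob_steps[:, step] = probs
            imp_map.loc[step, current] = norm_imp
            if len(current) == max(min_features, 1):
                break
            drop = current[int(np.argmin(mean_imp))]
            eliminated.append(drop)
            current = [f for f in current if f != drop]
            step += 1
        return RelapseLikelihoodResults(
            model=self,
            step_metrics=pd.DataFrame(steps),
            probabilities=prob_steps,
            importance_map=imp_map,
            eliminated=eliminated,
            final_features=current,
        )


# ---------------------------------------------------------------------------
# Results


@dataclass
class RelapseLikelihoodResults:
    """Fitted sweep: metrics, probabilities and importances per step.

    ``probabilities[:, s]`` is each patient's predicted likelihood of a
    not-seizure-free outcome at sweep step ``s`` (step 0 = all features);
    ``importance_map`` rows hold the normalized mean feature importances
    at each step (NaN once a feature has been eliminated).
    """

    model: RelapseLikelihoodModel
    step_metrics: pd.DataFrame
    probabilities: np.ndarray
    importance_map: pd.DataFrame
    eliminated: list
    final_features: list

    @property
    def n_steps(self) -> int:
        return len(self.step_metrics)

    def best_step(self) -> int:
        """Sweep step with the highest LOO AUC (first on ties)."""
        return int(np.argmax(self.step_metrics["auc"].to_numpy()))

    def mean_importances(self) -> pd.Series:
        """Feature importances averaged over the sweep steps where the
        feature was still present, normalized to [0, 1]."""
        m = self.importance_map.mean(axis=0, skipna=True)
        return m / m.max() if m.max() > 0 else m

    def summary(self) -> str:
        lines = [
            "Nested-LOO seizure-outcome prediction (linear SVM + RFE)",
            "=" * 60,
            f"patients: {self.model.table.n_patients} "
            f"(labeled: {int(self.model.table.labeled_mask.sum())})",
            f"sweep steps: {self.n_steps}",
            "",
            self.step_metrics.round(3).to_string(index=False),
            "",
            "Mean feature importance (normalized):",
            self.mean_importances().sort_values(ascending=False).round(3).to_string(),
        ]
        return "\n".join(lines)

    def plot_sweep(self, ax=None):
        """AUC across feature-elimination steps (matplotlib optional)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(1, self.n_steps + 1)
        ax.plot(x, self.step_metrics["auc"], marker="o", color="k")
        ax.set_xlabel("feature-elimination step")
        ax.set_ylabel("LOO AUC")
        ax.set_ylim(0, 1)
        return ax


# ---------------------------------------------------------------------------
# Relapse association


def relapse_association(
    probabilities,
    ilae,
    relapse: pd.DataFrame,
    n_perm: int = 1000,
    n_resamples: int = 10_000,
    seed: int = 0,
) -> dict:
    """Associate predicted relapse likelihood with outcomes over 5 years.

    Computes (1) the Spearman correlation between probability and year-1
    ILAE class with a robust-slope permutation test of the trend, and
    (2) for each follow-up year, a one-tailed exact rank-sum (relapse >
    no relapse) with Cohen's d and BCa CIs on the group medians. Relapse
    is defined only for patients at ILAE 1-2 at year 1; a year with fewer
    than 2 patients in either group is skipped with a warning.
    """
    p = np.asarray(probabilities, dtype=float)
    ilae = np.asarray(ilae, dtype=int)
    out: dict = {
        "ilae_spearman": spearman_rho(p, ilae),
        "ilae_slope": permutation_slope_test(ilae, p, n_perm=n_perm, seed=seed),
        "years": {},
    }
    for year in (2, 3, 4, 5):
        col = f"relapse_year{year}"
        if col not in relapse.columns:
            continue
        lab = relapse[col].to_numpy(dtype=float)
        eligible = ~np.isnan(lab) & (ilae <= 2)
        rel = p[eligible & (lab == 1)]
        norel = p[eligible & (lab == 0)]
        if rel.size < 2 or norel.size < 2:
            warnings.warn(f"year {year}: fewer than 2 patients in a group; skipped")
            continue
        rs = ranksum_exact(rel, norel, alternative="greater", exact_cap=60)
        try:
            d = cohen_d(rel, norel)
        except ValueError:  # degenerate spread within both groups
            d = float("nan")
        out["years"][year] = {
            "n_relapse": int(rel.size),
            "n_no_relapse": int(norel.size),
            "ranksum": rs,
            "cohen_d": d,
            "median_relapse": float(np.median(rel)),
            "median_no_relapse": float(np.median(norel)),
            "median_ci_relapse": bootstrap_ci_bca(
                rel, np.median, n_resamples=n_resamples, seed=seed + year
            ),
            "median_ci_no_relapse": bootstrap_ci_bca(
                norel, np.median, n_resamples=n_resamples, seed=seed + 10 + year
            ),
        }
    return out


def _fold_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-fold integer seeds below 2**31."""
    return np.random.SeedSequence([int(seed), 7]).generate_state(n) % (2**31 - 1)
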