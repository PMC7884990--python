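"""Synthetic cohort generator with planted network abnormalities.

Emulates the study design the pipeline targets: a normative control
cohort, a patient cohort whose gFA networks carry planted abnormal
subnetworks concentrated ipsilateral-temporally, patient-specific
surgery-affected edge sets, 13 clinical covariates, and ILAE outcome /
relapse labels driven by the abnormality load that survives surgery.
Ground truth (planted nodes/edges, true spared load, latent scores) is
recorded so every downstream stage can be validated offline.

All randomness flows from a single integer seed: the same configuration
reproduces the cohort byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .network import AREAS, Connectome, ConfigError
from .resection import ResectionEffect

#: Fraction of each hemisphere's nodes per anatomical area; loosely follows
#: lobar ROI counts of whole-brain cortical+subcortical parcellations.
_AREA_WEIGHTS = {
    "temporal": 0.25,
    "subcortical": 0.14,
    "parietal": 0.17,
    "occipital": 0.12,
    "frontal": 0.25,
    "cingulate": 0.07,
}

CLINICAL_COLUMNS = [
    "age_onset",
    "age_surgery",
    "duration",
    "n_AEDs",
    "sex",
    "side",
    "HS",
    "MRI_abnormal",
    "GTCS_history",
    "febrile_seizures",
    "family_history",
    "left_handed",
    "iq",
]


@dataclass
class OutcomeCoefs:
    """Ordered-logit outcome model on the true spared abnormality load.

    The latent score is ``intercept + spared_load * L + sum(clinical)``
    plus standard-logistic noise; ILAE class 1-5 falls out of the ordinal
    cut-points. Clinical covariates enter standardized (cohort z-scores).
    """

    intercept: float = -6.0
    spared_load: float = 1.2
    clinical: dict = field(
        default_factory=lambda: {"age_surgery": 0.25, "n_AEDs": 0.25}
    )
    cutpoints: tuple = (0.2, 1.4, 2.6, 3.8)


@dataclass
class RelapseCoefs:
    """Yearly relapse hazard (logistic in true spared load) for patients
    free of disabling seizures at year 1."""

    intercept: float = -4.5
    spared_load: float = 0.75


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort."""

    n_nodes: int = 114
    n_controls: int = 29
    n_patients: int = 51
    scaffold_density: float = 0.95
    edge_dropout: float = 0.08
    gfa_mean_range: tuple = (0.35, 0.65)
    gfa_sd_range: tuple = (0.025, 0.055)
    planted_nodes_per_patient: int = 8
    planted_effect: float = 4.0
    planted_sign: int = -1
    resection_area: str = "temporal"
    passthrough_fraction: float = 0.03
    outcome_coefs: OutcomeCoefs = field(default_factory=OutcomeCoefs)
    relapse_coefs: RelapseCoefs = field(default_factory=RelapseCoefs)
    #: probability that a non-resected planted node is ipsilateral
    ipsilateral_bias: float = 0.7
    #: multinomial over follow-up horizon {2, 3, 4, 5} years
    followup_probs: tuple = (0.12, 0.16, 0.12, 0.60)
    #: node-percentage cut (fraction) defining ground-truth abnormal nodes
    truth_node_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_nodes", "n_controls", "n_patients", "planted_nodes_per_patient"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_nodes < 2 or self.n_nodes % 2:
            raise ConfigError(f"n_nodes must be an even integer >= 2, got {self.n_nodes}")
        for name in ("scaffold_density", "edge_dropout", "passthrough_fraction",
                     "ipsilateral_bias", "truth_node_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("gfa_mean_range", "gfa_sd_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi < 1):
                raise ConfigError(f"{name} must satisfy 0 < lo <= hi < 1, got {(lo, hi)}")
        if self.resection_area not in AREAS:
            raise ConfigError(
                f"resection_area must be one of {AREAS}, got {self.resection_area!r}"
            )
        if self.planted_sign not in (-1, 1):
            raise ConfigError(f"planted_sign must be +1 or -1, got {self.planted_sign}")
        if abs(sum(self.followup_probs) - 1.0) > 1e-9 or len(self.followup_probs) != 4:
            raise ConfigError("followup_probs must be 4 probabilities summing to 1")


@dataclass
class GroundTruth:
    """Planted abnormality bookkeeping for one synthetic patient."""

    patient_id: str
    planted_nodes: list
    planted_edges: set          # unordered label pairs, present in the patient
    affected_edges: set         # copy of the surgery-affected set
    true_pre_load: int
    true_spared_load: int
    latent_score: float = float("nan")


@dataclass
class Scaffold:
    """Shared edge topology and per-edge gFA population parameters."""

    nodes: pd.DataFrame
    edges: np.ndarray           # boolean (n, n), symmetric
    mu: np.ndarray              # per-edge population mean gFA
    sigma: np.ndarray           # per-edge population SD
    log_streamline: np.ndarray  # per-edge log-normal location for counts


@dataclass
class SyntheticCohort:
    config: GeneratorConfig
    scaffold: Scaffold
    controls: list
    patients: list
    effects: list               # ResectionEffect per patient
    truths: list                # GroundTruth per patient
    clinical: pd.DataFrame
    outcomes: pd.DataFrame

    @property
    def nodes(self) -> pd.DataFrame:
        return self.scaffold.nodes


# ---------------------------------------------------------------------------
# Parcellation and scaffold


def make_node_table(n_nodes: int) -> pd.DataFrame:
    """Synthetic parcellation: n/2 nodes per hemisphere, areas distributed
    by largest remainder according to typical lobar proportions."""
    if n_nodes < 2 or n_nodes % 2:
        raise ConfigError(f"n_nodes must be an even integer >= 2, got {n_nodes}")
    per_hemi = n_nodes // 2
    weights = np.array([_AREA_WEIGHTS[a] for a in AREAS])
    raw = weights * per_hemi
    counts = np.floor(raw).astype(int)
    remainder = per_hemi - counts.sum()
    for i in np.argsort(raw - counts)[::-1][:remainder]:
        counts[i] += 1
    rows = []
    for hemi, prefix in (("left", "L"), ("right", "R")):
        k = 0
        for area, c in zip(AREAS, counts):
            for _ in range(c):
                k += 1
                rows.append((f"{prefix}{k:03d}", hemi, area))
    return pd.DataFrame(rows, columns=["label", "hemisphere", "area"])


def build_scaffold(cfg: GeneratorConfig, rng: np.random.Generator) -> Scaffold:
    nodes = make_node_table(cfg.n_nodes)
    n = cfg.n_nodes
    upper = np.triu(rng.random((n, n)) < cfg.scaffold_density, 1)
    edges = upper | upper.T
    lo, hi = cfg.gfa_mean_range
    mu = np.triu(rng.uniform(lo, hi, (n, n)), 1)
    lo, hi = cfg.gfa_sd_range
    sigma = np.triu(rng.uniform(lo, hi, (n, n)), 1)
    logs = np.triu(rng.normal(3.0, 0.8, (n, n)), 1)
    mu, sigma, logs = mu + mu.T, sigma + sigma.T, logs + logs.T
    for m in (mu, sigma, logs):
        m[~edges] = np.nan
    return Scaffold(nodes=nodes, edges=edges, mu=mu, sigma=sigma, log_streamline=logs)


def _draw_subject(
    scaffold: Scaffold,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    subject_id: str,
    mu_shift: np.ndarray | None = None,
) -> Connectome:
    """One subject from the shared generative model.

    Each scaffold edge is present with probability 1 - edge_dropout; its
    gFA is Normal(mu_ij (+ shift), sigma_ij) truncated to (0, 1) and its
    streamline count log-normal (always >= 1 where the edge is present).
    """
    n = len(scaffold.nodes)
    upper = np.triu(scaffold.edges, 1)
    present_u = upper & (np.triu(rng.random((n, n)), 1) >= cfg.edge_dropout)

    mu = scaffold.mu.copy()
    if mu_shift is not None:
        mu = mu + mu_shift
    eps = 1e-6
    iu = np.where(present_u)
    m, s = mu[iu], scaffold.sigma[iu]
    a, b = (eps - m) / s, (1 - eps - m) / s
    gfa_vals = truncnorm.rvs(a, b, loc=m, scale=s, random_state=rng)
    counts = np.maximum(
        1, np.rint(np.exp(rng.normal(scaffold.log_streamline[iu], 0.3)))
    ).astype(int)

    gfa = np.full((n, n), np.nan)
    streamlines = np.zeros((n, n), dtype=int)
    gfa[iu] = gfa_vals
    streamlines[iu] = counts
    gfa[(iu[1], iu[0])] = gfa_vals
    streamlines[(iu[1], iu[0])] = counts
    return Connectome(
        nodes=scaffold.nodes, streamlines=streamlines, gfa=gfa, subject_id=subject_id
    )


# ---------------------------------------------------------------------------
# Controls and patients


def generate_controls(
    cfg: GeneratorConfig,
    scaffold: Scaffold | None = None,
    rng: np.random.Generator | None = None,
) -> list:
    """Generate the control cohort (and the scaffold if not supplied)."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    if scaffold is None:
        scaffold = build_scaffold(cfg, rng)
    return [
        _draw_subject(scaffold, cfg, rng, f"control{i + 1:03d}")
        for i in range(cfg.n_controls)
    ]


def generate_patient(
    cfg: GeneratorConfig,
    scaffold: Scaffold,
    planted_nodes,
    rng: np.random.Generator,
    surgery_side: str = "left",
    patient_id: str = "patient",
) -> tuple[Connectome, ResectionEffect, GroundTruth]:
    """Draw one patient with a planted abnormal subnetwork.

    Every scaffold edge incident to a planted node has its population gFA
    mean shifted by ``planted_sign * planted_effect * sigma_ij`` (reduced
    anisotropy by default). The surgery-affected set contains every
    patient edge incident to a resected-area node on the surgery side,
    plus a ``passthrough_fraction`` random sample of the remaining edges
    (streamlines that merely pass through the resection cavity).
    """
    labels = scaffold.nodes["label"].tolist()
    index = {lab: i for i, lab in enumerate(labels)}
    unknown = [p for p in planted_nodes if p not in index]
    if unknown:
        raise ValueError(f"planted nodes outside parcellation: {unknown}")
    planted_idx = np.array(sorted(index[p] for p in planted_nodes), dtype=int)

    n = len(labels)
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[planted_idx] = True
    incident = (planted_mask[:, None] | planted_mask[None, :]) & scaffold.edges
    shift = np.where(incident, cfg.planted_sign * cfg.planted_effect * scaffold.sigma, 0.0)

    patient = _draw_subject(scaffold, cfg, rng, patient_id, mu_shift=shift)
    present = patient.present

    resected = (
        (scaffold.nodes["hemisphere"] == surgery_side)
        & (scaffold.nodes["area"] == cfg.resection_area)
    ).to_numpy()
    res_incident = (resected[:, None] | resected[None, :]) & present
    other = present & ~res_incident
    iu, ju = np.where(np.triu(other, 1))
    n_extra = int(round(cfg.passthrough_fraction * iu.size))
    pick = rng.choice(iu.size, size=n_extra, replace=False) if n_extra else []
    affected = {
        tuple(sorted((labels[i], labels[j])))
        for i, j in zip(*np.where(np.triu(res_incident, 1)))
    }
    affected |= {tuple(sorted((labels[iu[k]], labels[ju[k]]))) for k in pick}
    effect = ResectionEffect(affected=affected, side=surgery_side)

    planted_edges = {
        tuple(sorted((labels[i], labels[j])))
        for i, j in zip(*np.where(np.triu(incident & present, 1)))
    }
    pre_load, spared_load = _true_loads(
        patient, planted_edges, effect.affected, cfg.truth_node_fraction
    )
    truth = GroundTruth(
        patient_id=patient_id,
        planted_nodes=sorted(planted_nodes),
        planted_edges=planted_edges,
        affected_edges=set(effect.affected),
        true_pre_load=pre_load,
        true_spared_load=spared_load,
    )
    return patient, effect, truth


def _true_loads(
    patient: Connectome,
    planted_edges: set,
    affected: set,
    node_fraction: float,
) -> tuple[int, int]:
    """Noiseless abnormality loads implied by the planted edge set.

    A node is truly abnormal when at least ``node_fraction`` of its
    present-edge degree is planted (and, for the spared variant, not
    surgery-affected). Recomputable from the ground-truth sets alone.
    """
    labels = patient.labels
    index = {lab: i for i, lab in enumerate(labels)}
    k = patient.present.sum(axis=1)
    a_pre = np.zeros(len(labels))
    a_spared = np.zeros(len(labels))
    for aa, bb in planted_edges:
        i, j = index[aa], index[bb]
        a_pre[i] += 1
        a_pre[j] += 1
        if (aa, bb) not in affected:
            a_spared[i] += 1
            a_spared[j] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        pre = (k > 0) & (a_pre / np.maximum(k, 1) >= node_fraction)
        spared = (k > 0) & (a_spared / np.maximum(k, 1) >= node_fraction)
    return int(pre.sum()), int(spared.sum())


# ---------------------------------------------------------------------------
# Clinical covariates and outcomes


def generate_clinical(
    cfg: GeneratorConfig, rng: np.random.Generator, sides: list
) -> pd.DataFrame:
    """13 generic clinical covariates per patient (emulation, not a
    reproduction of any real cohort table)."""
    m = cfg.n_patients
    age_onset = np.clip(rng.normal(12, 7, m), 0.5, 45).round(1)
    duration = np.clip(rng.lognormal(2.9, 0.5, m), 1, 45).round(1)
    df = pd.DataFrame(
        {
            "patient_id": [f"patient{i + 1:03d}" for i in range(m)],
            "age_onset": age_onset,
            "age_surgery": (age_onset + duration).round(1),
            "duration": duration,
            "n_AEDs": rng.poisson(1.6, m) + 1,
            "sex": rng.integers(0, 2, m),
            "side": (np.asarray(sides) == "left").astype(int),
            "HS": rng.binomial(1, 0.6, m),
            "MRI_abnormal": rng.binomial(1, 0.8, m),
            "GTCS_history": rng.binomial(1, 0.5, m),
            "febrile_seizures": rng.binomial(1, 0.3, m),
            "family_history": rng.binomial(1, 0.15, m),
            "left_handed": rng.binomial(1, 0.12, m),
            "iq": np.clip(rng.normal(95, 12, m), 60, 140).round(0),
        }
    )
    return df


def assign_outcomes(
    truths: list,
    clinical: pd.DataFrame,
    cfg: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """ILAE year-1 class and yearly relapse labels from the ground truth.

    Latent ordered-logit score: higher true spared abnormality load (and
    configured clinical covariates, standardized) pushes patients toward
    ILAE 3-5. Patients at ILAE 1-2 then face a yearly relapse hazard,
    logistic in the true spared load, over their follow-up horizon;
    follow-up is truncated per patient (censored years are missing).
    """
    if len(truths) != len(clinical):
        raise ConfigError("one ground truth per clinical row required")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    oc, rc = cfg.outcome_coefs, cfg.relapse_coefs

    loads = np.array([t.true_spared_load for t in truths], dtype=float)
    score = oc.intercept + oc.spared_load * loads
    for col, coef in oc.clinical.items():
        vals = clinical[col].to_numpy(dtype=float)
        sd = vals.std()
        if sd > 0:
            score = score + coef * (vals - vals.mean()) / sd
    noise = rng.logistic(0, 1, size=len(truths))
    latent = score + noise
    cut = np.asarray(oc.cutpoints, dtype=float)
    ilae = 1 + (latent[:, None] > cut[None, :]).sum(axis=1)

    followup = rng.choice([2, 3, 4, 5], size=len(truths), p=cfg.followup_probs)
    hazard = 1.0 / (1.0 + np.exp(-(rc.intercept + rc.spared_load * loads)))
    relapse_draws = rng.random((len(truths), 4)) < hazard[:, None]  # years 2..5

    rows = {}
    for year in (2, 3, 4, 5):
        col = np.full(len(truths), np.nan)
        for i, t in enumerate(truths):
            t.latent_score = float(latent[i])
            if ilae[i] >= 3:
                continue  # relapse defined only for ILAE 1-2 at year 1
            observed = min(followup[i], 5)
            hit_years = [y for y in range(2, observed + 1) if relapse_draws[i, y - 2]]
            relapse_year = hit_years[0] if hit_years else None
            if relapse_year is not None and relapse_year <= year:
                col[i] = 1.0
            elif observed >= year:
                col[i] = 0.0
        rows[f"relapse_year{year}"] = col

    out = pd.DataFrame(
        {
            "patient_id": clinical["patient_id"].to_numpy(),
            "ilae_year1": ilae,
            "followup_years": followup,
            **rows,
        }
    )
    return out


# ---------------------------------------------------------------------------
# Whole cohort


def generate_cohort(cfg: GeneratorConfig) -> SyntheticCohort:
    """Generate the complete synthetic study: controls, patients with
    planted abnormalities, resections, clinical table, and outcomes."""
    cfg.validate()
    ss = np.random.SeedSequence([cfg.seed, 1])
    rng_scaffold, rng_controls, rng_patients, rng_clinical, rng_outcome = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    scaffold = build_scaffold(cfg, rng_scaffold)
    controls = generate_controls(cfg, scaffold=scaffold, rng=rng_controls)

    nodes = scaffold.nodes
    patients, effects, truths, sides = [], [], [], []
    for i in range(cfg.n_patients):
        side = "left" if rng_patients.random() < 0.5 else "right"
        planted = _choose_planted_nodes(cfg, nodes, side, rng_patients)
        pid = f"patient{i + 1:03d}"
        patient, effect, truth = generate_patient(
            cfg, scaffold, planted, rng_patients, surgery_side=side, patient_id=pid
        )
        patients.append(patient)
        effects.append(effect)
        truths.append(truth)
        sides.append(side)

    clinical = generate_clinical(cfg, rng_clinical, sides)
    outcomes = assign_outcomes(truths, clinical, cfg, rng=rng_outcome)
    return SyntheticCohort(
        config=cfg,
        scaffold=scaffold,
        controls=controls,
        patients=patients,
        effects=effects,
        truths=truths,
        clinical=clinical,
        outcomes=outcomes,
    )


def _choose_planted_nodes(
    cfg: GeneratorConfig,
    nodes: pd.DataFrame,
    surgery_side: str,
    rng: np.random.Generator,
) -> list:
    """Planted node set for one patient.

    A uniformly drawn fraction of the planted nodes lies inside the
    to-be-resected area (those abnormalities are removed by surgery);
    the remainder is placed preferentially ipsilaterally elsewhere. The
    across-patient spread in the surviving (spared) planted count is what
    drives the outcome distribution.
    """
    labels = nodes["label"].to_numpy()
    in_resection = (
        (nodes["hemisphere"] == surgery_side) & (nodes["area"] == cfg.resection_area)
    ).to_numpy()
    ipsi_out = ((nodes["hemisphere"] == surgery_side).to_numpy()) & ~in_resection
    contra = (nodes["hemisphere"] != surgery_side).to_numpy()

    total = cfg.planted_nodes_per_patient
    n_inside = min(int(round(total * rng.random())), int(in_resection.sum()))
    chosen = list(rng.choice(labels[in_resection], size=n_inside, replace=False))
    for _ in range(total - n_inside):
        pool = ipsi_out if rng.random() < cfg.ipsilateral_bias else contra
        avail = [l for l in labels[pool] if l not in chosen]
        chosen.append(avail[rng.integers(len(avail))])
    return sorted(chosen)
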