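"""End-to-end orchestration: cohort -> z-networks -> grids -> prediction.

`run_pipeline` executes every stage on a cohort directory (or an
in-memory synthetic cohort), writes all stage outputs as delimited text,
and records provenance (seed, config hash, stage timings). Outputs are
deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abnormality import ThresholdGrid, abnormal_node_set, load_grid
from .io import CohortOnDisk, write_cohort
from .predict import (
    FeatureTable,
    PredictConfig,
    RelapseLikelihoodModel,
    relapse_association,
)
from .regional import area_proportion_change, reduction_comparison
from .resection import apply_resection
from .standardize import build_reference, z_score_network
from .synthetic import CLINICAL_COLUMNS, SyntheticCohort


@dataclass
class PipelineConfig:
    min_controls: int = 10
    tau_z: float = 2.8
    tau_p: float = 10.0
    edge_rule: str = "abs"
    relapse_n_perm: int = 1000
    relapse_n_resamples: int = 2000
    predict: PredictConfig = field(default_factory=PredictConfig)
    seed: int = 0

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload["predict"]["c_grid"] = list(np.asarray(payload["predict"]["c_grid"]))
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    reference: object
    pre_znets: list
    spared_znets: list
    pre_grids: list
    spared_grids: list
    loads: pd.DataFrame
    regional: dict
    reduction: dict
    prediction: object          # RelapseLikelihoodResults
    relapse: dict
    provenance: dict


def _stage(provenance: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            provenance["stage_seconds"][name] = round(time.perf_counter() - self.t0, 3)
            return False

    return _Timer()


def run_pipeline(
    cohort, config: PipelineConfig | None = None, out_dir=None
) -> PipelineResult:
    """Run every analysis stage on a cohort.

    Parameters
    ----------
    cohort : SyntheticCohort, CohortOnDisk, or path to a cohort directory
    config : PipelineConfig
    out_dir : optional directory for stage outputs (TSV/CSV + provenance)
    """
    config = config or PipelineConfig()
    if isinstance(cohort, (str, Path)):
        cohort = CohortOnDisk(cohort)

    provenance = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "stage_seconds": {},
    }

    if isinstance(cohort, SyntheticCohort):
        controls = cohort.controls
        patients = cohort.patients
        effects = cohort.effects
        clinical = cohort.clinical
        outcomes = cohort.outcomes
    else:
        controls = cohort.controls()
        patients = [cohort.patient(pid) for pid in cohort.patient_ids]
        effects = [cohort.effect(pid) for pid in cohort.patient_ids]
        order = [p.subject_id for p in patients]
        clinical = cohort.clinical.set_index("patient_id").loc[order].reset_index()
        outcomes = cohort.outcomes.set_index("patient_id").loc[order].reset_index()

    with _stage(provenance, "reference"):
        reference = build_reference(controls)

    pre_znets, spared_znets = [], []
    with _stage(provenance, "zscore"):
        for patient, effect in zip(patients, effects):
            try:
                zn = z_score_network(patient, reference, config.min_controls)
                pre_znets.append(zn)
                spared_znets.append(apply_resection(zn, effect))
            except Exception as exc:  # noqa: BLE001 - annotate subject then re-raise
                raise RuntimeError(
                    f"stage zscore failed for subject {patient.subject_id}: {exc}"
                ) from exc

    grid = ThresholdGrid()
    with _stage(provenance, "abnormality"):
        pre_grids = [load_grid(z, grid, config.edge_rule) for z in pre_znets]
        spared_grids = [load_grid(z, grid, config.edge_rule) for z in spared_znets]
        loads = pd.DataFrame(
            {
                "patient_id": [p.subject_id for p in patients],
                "pre_load": [g.load_at(config.tau_z, config.tau_p) for g in pre_grids],
                "spared_load": [
                    g.load_at(config.tau_z, config.tau_p) for g in spared_grids
                ],
            }
        )

    ilae = outcomes["ilae_year1"].to_numpy(dtype=int)
    sides = [e.side for e in effects]
    with _stage(provenance, "regional"):
        regional = {}
        nodes = patients[0].nodes
        for group_name, mask in (("ILAE1", ilae == 1), ("ILAE3plus", ilae >= 3)):
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            pre_sets = [
                abnormal_node_set(pre_znets[i], config.tau_z, config.tau_p,
                                  config.edge_rule)
                for i in idx
            ]
            spared_sets = [
                abnormal_node_set(spared_znets[i], config.tau_z, config.tau_p,
                                  config.edge_rule)
                for i in idx
            ]
            regional[group_name] = area_proportion_change(
                pre_sets, spared_sets, nodes, [sides[i] for i in idx]
            )
        labeled = (ilae == 1) | (ilae >= 3)
        groups = ilae[labeled] == 1
        if groups.any() and not groups.all():
            reduction = reduction_comparison(
                loads["pre_load"].to_numpy()[labeled],
                loads["spared_load"].to_numpy()[labeled],
                groups,
            )
        else:
            reduction = {}

    with _stage(provenance, "predict"):
        relapse_cols = [c for c in outcomes.columns if c.startswith("relapse_year")]
        table = FeatureTable(
            clinical=clinical[[c for c in CLINICAL_COLUMNS if c in clinical.columns]],
            pre_grids=pre_grids,
            spared_grids=spared_grids,
            ilae=ilae,
            relapse=outcomes[relapse_cols] if relapse_cols else None,
        )
        model = RelapseLikelihoodModel(table, config.predict)
        prediction = model.fit()

    with _stage(provenance, "relapse"):
        spared_only = model.loo_probabilities(["spared_load"])
        relapse = relapse_association(
            spared_only,
            ilae,
            table.relapse if table.relapse is not None else pd.DataFrame(),
            n_perm=config.relapse_n_perm,
            n_resamples=config.relapse_n_resamples,
            seed=config.seed,
        )
        relapse["probabilities"] = spared_only

    result = PipelineResult(
        reference=reference,
        pre_znets=pre_znets,
        spared_znets=spared_znets,
        pre_grids=pre_grids,
        spared_grids=spared_grids,
        loads=loads,
        regional=regional,
        reduction=reduction,
        prediction=prediction,
        relapse=relapse,
        provenance=provenance,
    )
    if out_dir is not None:
        _write_outputs(result, out_dir, config)
    return result


def _write_outputs(result: PipelineResult, out_dir, config: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.loads.to_csv(out / "abnormality_loads.csv", index=False)
    for group, df in result.regional.items():
        df.to_csv(out / f"regional_{group}.tsv", sep="\t", index=False)
    result.prediction.step_metrics.to_csv(out / "sweep_metrics.tsv", sep="\t",
                                          index=False)
    result.prediction.importance_map.to_csv(out / "importance_map.tsv", sep="\t")
    probs = pd.DataFrame(
        result.prediction.probabilities,
        index=result.loads["patient_id"],
        columns=[f"step{s + 1}" for s in range(result.prediction.n_steps)],
    )
    probs.to_csv(out / "probabilities.csv")
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=1))
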