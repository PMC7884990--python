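"""Normative z-scoring of patient connectomes against a control cohort.

Deterministic tractography yields sparse networks whose edges are only
partially shared across subjects, so the control reference is estimated
per edge over the controls that actually possess the edge, and a patient
edge is standardized only when enough controls carry it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import Connectome, ZNetwork


@dataclass
class ControlReference:
    """Per-edge control statistics used for z-scoring.

    ``count[i, j]`` is the number of controls with streamlines on (i, j);
    ``mean`` and ``sd`` are the sample mean and sample SD (n-1 denominator)
    of gFA over those controls, NaN where fewer than two controls possess
    the edge.
    """

    nodes: pd.DataFrame
    count: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_controls: int

    @property
    def labels(self) -> list[str]:
        return self.nodes["label"].tolist()


def build_reference(controls: list[Connectome]) -> ControlReference:
    """Estimate the per-edge normative distribution from control subjects.

    Parameters
    ----------
    controls : list of Connectome
        At least two control networks sharing an identical node ordering.

    Returns
    -------
    ControlReference
    """
    if len(controls) < 2:
        raise ValueError("need at least 2 controls to build a reference")
    labels = controls[0].labels
    for c in controls[1:]:
        if c.labels != labels:
            offending = sorted(set(c.labels) ^ set(labels))
            raise ValueError(f"control node sets differ; offending labels: {offending}")

    present = np.stack([c.present for c in controls])        # (m, n, n)
    gfa = np.stack([c.gfa for c in controls])                # NaN where absent
    count = present.sum(axis=0)

    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-absent edges
        mean = np.nanmean(np.where(present, gfa, np.nan), axis=0)
        sd = np.nanstd(np.where(present, gfa, np.nan), axis=0, ddof=1)
    mean[count < 2] = np.nan
    sd[count < 2] = np.nan
    return ControlReference(
        nodes=controls[0].nodes,
        count=count,
        mean=mean,
        sd=sd,
        n_controls=len(controls),
    )


def z_score_network(
    patient: Connectome,
    ref: ControlReference,
    min_controls: int = 10,
) -> ZNetwork:
    """Standardize a patient connectome edge-wise against the reference.

    An edge is z-scored when the patient possesses it, at least
    ``min_controls`` controls possess it, and the control SD is positive;
    all other node pairs are marked invalid. Absence of an edge in the
    patient is not treated as abnormality. Node degrees are the counts of
    valid edges and define the presurgical degree used downstream.
    """
    if patient.labels != ref.labels:
        offending = sorted(set(patient.labels) ^ set(ref.labels))
        raise ValueError(f"patient nodes do not match reference: {offending}")
    if min_controls > ref.n_controls:
        raise ValueError(
            f"min_controls={min_controls} exceeds the {ref.n_controls} controls "
            "in the reference"
        )

    valid = patient.present & (ref.count >= min_controls)
    with np.errstate(invalid="ignore"):
        valid &= np.nan_to_num(ref.sd, nan=0.0) > 0
    z = np.full_like(ref.mean, np.nan)
    z[valid] = (patient.gfa[valid] - ref.mean[valid]) / ref.sd[valid]
    degrees = valid.sum(axis=1)
    return ZNetwork(
        nodes=patient.nodes,
        z=z,
        valid=valid,
        degrees=degrees,
        kind="presurgery",
        subject_id=patient.subject_id,
    )
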