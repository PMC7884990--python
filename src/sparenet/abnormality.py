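"""Node abnormality and abnormality load over a 2-D threshold grid.

An edge is abnormal when its |z| reaches the z threshold tau_z; a node is
abnormal when at least tau_p percent of its presurgical-degree links are
abnormal. The abnormality load is the count of abnormal nodes, evaluated
over a grid of (tau_z, tau_p) pairs; the discriminatory pair for a
training group is the grid cell with the highest rank-based AUC between
outcome groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .network import ZNetwork

#: How edge z-scores are converted to abnormality flags.
EDGE_RULES = ("abs", "negative-only", "positive-only")


@dataclass(frozen=True)
class ThresholdGrid:
    """The default 25 x 50 grid: tau_z 2.1..4.5 by 0.1, tau_p 1%..50% by 1%.

    Grid values are generated by integer indexing to avoid floating-point
    accumulation error.
    """

    tau_z: np.ndarray = field(default_factory=lambda: np.arange(21, 46) / 10.0)
    tau_p: np.ndarray = field(default_factory=lambda: np.arange(1, 51, dtype=float))

    def __post_init__(self) -> None:
        for name in ("tau_z", "tau_p"):
            vals = getattr(self, name)
            if len(vals) < 1 or np.any(np.diff(vals) <= 0):
                raise ValueError(f"{name} values must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.tau_z), len(self.tau_p)


@dataclass
class NodeAbnormality:
    """Per-node abnormal-link counts and percentages at one tau_z."""

    abnormal_links: np.ndarray   # a_i
    degrees: np.ndarray          # presurgical k_i
    percentage: np.ndarray       # 100 * a_i / k_i, 0 where k_i == 0
    tau_z: float


@dataclass
class AbnormalityGrid:
    """Abnormality load at every grid cell for one network."""

    grid: ThresholdGrid
    load: np.ndarray             # shape (len(tau_z), len(tau_p)), int

    def load_at(self, tau_z: float, tau_p: float) -> int:
        iz = int(np.argmin(np.abs(self.grid.tau_z - tau_z)))
        ip = int(np.argmin(np.abs(self.grid.tau_p - tau_p)))
        return int(self.load[iz, ip])


def _edge_flags(zn: ZNetwork, tau_z: float, rule: str) -> np.ndarray:
    if rule not in EDGE_RULES:
        raise ValueError(f"unknown edge rule {rule!r}")
    z = np.where(zn.valid, zn.z, np.nan)
    with np.errstate(invalid="ignore"):
        if rule == "abs":
            flags = np.abs(z) >= tau_z
        elif rule == "negative-only":
            flags = z <= -tau_z
        else:
            flags = z >= tau_z
    return flags & zn.valid


def node_abnormality_profile(
    zn: ZNetwork, tau_z: float, rule: str = "abs"
) -> NodeAbnormality:
    """Count abnormal links per node and normalize by presurgical degree.

    ``p_i = 100 * a_i / k_i`` with ``p_i = 0`` when a node has no
    assessable presurgical links (e.g. fully resected nodes).
    """
    if tau_z <= 0:
        raise ValueError("tau_z must be positive")
    a = _edge_flags(zn, tau_z, rule).sum(axis=1)
    k = zn.degrees
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(k > 0, 100.0 * a / np.maximum(k, 1), 0.0)
    return NodeAbnormality(abnormal_links=a, degrees=k, percentage=p, tau_z=tau_z)


def abnormality_load(
    profile: NodeAbnormality, tau_p: float
) -> tuple[int, np.ndarray]:
    """Abnormal-node set and its cardinality at a percentage threshold.

    Both thresholds are inclusive: a node is abnormal when
    ``p_i >= tau_p``.
    """
    if not 0 < tau_p <= 100:
        raise ValueError("tau_p must lie in (0, 100]")
    flags = profile.percentage >= tau_p
    return int(flags.sum()), np.flatnonzero(flags)


def abnormal_node_set(
    zn: ZNetwork, tau_z: float, tau_p: float, rule: str = "abs"
) -> np.ndarray:
    """Indices of abnormal nodes at a single threshold pair."""
    profile = node_abnormality_profile(zn, tau_z, rule)
    _, nodes = abnormality_load(profile, tau_p)
    return nodes


def load_grid(
    zn: ZNetwork, grid: ThresholdGrid | None = None, rule: str = "abs"
) -> AbnormalityGrid:
    """Abnormality load at every (tau_z, tau_p) grid cell.

    Vectorized over the grid; equivalent to calling
    :func:`node_abnormality_profile` and :func:`abnormality_load` cell by
    cell.
    """
    if grid is None:
        grid = ThresholdGrid()
    z = np.where(zn.valid, zn.z, np.nan)
    with np.errstate(invalid="ignore"):
        if rule == "abs":
            score = np.abs(z)
        elif rule == "negative-only":
            score = -z
        elif rule == "positive-only":
            score = z
        else:
            raise ValueError(f"unknown edge rule {rule!r}")
    score = np.where(zn.valid, score, -np.inf)

    # a: (n_tau_z, n_nodes) abnormal-link counts
    a = (score[None, :, :] >= grid.tau_z[:, None, None]).sum(axis=2)
    k = np.maximum(zn.degrees, 1)
    p = np.where(zn.degrees > 0, 100.0 * a / k, 0.0)
    load = (p[:, None, :] >= grid.tau_p[None, :, None]).sum(axis=2)
    return AbnormalityGrid(grid=grid, load=load.astype(int))


def pairwise_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC of ``values`` for the positive class; ties count 1/2."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(values)
    return (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def select_threshold_pair(
    grids: list[AbnormalityGrid], labels
) -> tuple[float, float, float]:
    """Pick the most discriminatory (tau_z, tau_p) for a training group.

    For every grid cell, the rank-based AUC of abnormality load against
    the binary outcome labels is computed across the training patients;
    the cell with the highest AUC wins, with deterministic tie-breaking
    toward the lowest tau_z, then the lowest tau_p.

    Returns
    -------
    (tau_z, tau_p, auc)
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("threshold selection needs both outcome classes")
    if len(grids) != labels.size:
        raise ValueError("one grid per labeled patient required")
    grid = grids[0].grid
    loads = np.stack([g.load.ravel() for g in grids])        # (n_patients, cells)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(loads, axis=0)
    aucs = (ranks[labels].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n0)
    best = int(np.argmax(aucs))  # first max: lowest tau_z, then lowest tau_p
    iz, ip = divmod(best, len(grid.tau_p))
    return float(grid.tau_z[iz]), float(grid.tau_p[ip]), float(aucs[best])
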