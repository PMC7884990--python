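"""Core network containers.

Weighted structural connectomes are stored as dense symmetric matrices with
an accompanying node-metadata table (label, hemisphere, anatomical area).
Edges carry two weights: a streamline count (topology) and a mean
generalized fractional anisotropy (gFA) in (0, 1); the gFA weight is
defined exactly where the streamline count is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")
AREAS = ("temporal", "subcortical", "parietal", "occipital", "frontal", "cingulate")


class ConfigError(ValueError):
    """Invalid configuration value; the message names the offending field."""


def _as_node_table(nodes: pd.DataFrame) -> pd.DataFrame:
    required = {"label", "hemisphere", "area"}
    missing = required - set(nodes.columns)
    if missing:
        raise ValueError(f"node table missing columns: {sorted(missing)}")
    bad_hemi = set(nodes["hemisphere"]) - set(HEMISPHERES)
    if bad_hemi:
        raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
    bad_area = set(nodes["area"]) - set(AREAS)
    if bad_area:
        raise ValueError(f"unknown area labels: {sorted(bad_area)}")
    if nodes["label"].duplicated().any():
        dups = nodes.loc[nodes["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate node labels: {dups}")
    return nodes.reset_index(drop=True)


@dataclass
class Connectome:
    """A single subject's weighted structural brain network.

    Parameters
    ----------
    nodes : pandas.DataFrame
        One row per region of interest with columns ``label``,
        ``hemisphere`` (left/right) and ``area`` (one of the six lobar
        groupings used throughout the package).
    streamlines : ndarray of shape (n, n)
        Symmetric non-negative integer streamline counts, zero diagonal.
    gfa : ndarray of shape (n, n)
        Symmetric mean-gFA weights in (0, 1) where ``streamlines > 0``
        and NaN elsewhere.
    """

    nodes: pd.DataFrame
    streamlines: np.ndarray
    gfa: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.nodes = _as_node_table(self.nodes)
        n = len(self.nodes)
        self.streamlines = np.asarray(self.streamlines)
        self.gfa = np.asarray(self.gfa, dtype=float)
        if self.streamlines.shape != (n, n) or self.gfa.shape != (n, n):
            raise ValueError(
                f"matrix shape mismatch: {self.streamlines.shape}, {self.gfa.shape} "
                f"for {n} nodes"
            )
        if (self.streamlines < 0).any():
            raise ValueError("negative streamline count")
        if not np.array_equal(self.streamlines, self.streamlines.T):
            raise ValueError("streamline matrix is not symmetric")
        present = self.streamlines > 0
        np.fill_diagonal(present, False)
        if np.diag(self.streamlines).any():
            raise ValueError("nonzero diagonal in streamline matrix")
        defined = np.isfinite(self.gfa)
        if (defined != present).any():
            raise ValueError("gFA must be defined exactly where streamlines > 0")
        vals = self.gfa[present]
        if vals.size and ((vals <= 0) | (vals >= 1)).any():
            raise ValueError("gFA weights must lie strictly in (0, 1)")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def labels(self) -> list[str]:
        return self.nodes["label"].tolist()

    @property
    def present(self) -> np.ndarray:
        """Boolean edge-presence matrix (streamline count > 0)."""
        mask = self.streamlines > 0
        np.fill_diagonal(mask, False)
        return mask


@dataclass
class ZNetwork:
    """A patient network standardized edge-wise against controls.

    ``z[i, j]`` is the number of control standard deviations the patient's
    gFA weight lies from the control mean; it is defined only on the
    ``valid`` mask. ``degrees`` holds each node's presurgical degree, i.e.
    the count of valid edges at construction time; it is carried unchanged
    into surgically spared variants so that node abnormality percentages
    remain fractions of the originally assessable links.
    """

    nodes: pd.DataFrame
    z: np.ndarray
    valid: np.ndarray
    degrees: np.ndarray
    kind: str = "presurgery"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.nodes = _as_node_table(self.nodes)
        if self.kind not in ("presurgery", "spared"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        self.z = np.asarray(self.z, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.degrees = np.asarray(self.degrees, dtype=int)
        n = len(self.nodes)
        if self.z.shape != (n, n) or self.valid.shape != (n, n):
            raise ValueError("z/valid shape mismatch with node table")
        if self.degrees.shape != (n,):
            raise ValueError("degree vector length mismatch")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def labels(self) -> list[str]:
        return self.nodes["label"].tolist()

    def edge_count(self) -> int:
        """Number of valid (unordered) edges."""
        return int(np.triu(self.valid, 1).sum())
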