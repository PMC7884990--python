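"""Virtual resection: construct the surgically spared z-network.

Surgery can only remove streamlines, so the spared network is the
presurgery network restricted to edges whose streamlines avoid the
resection. The surgery-affected edge set is an input (derived upstream
from imaging, or planted by the synthetic cohort generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import ZNetwork


@dataclass
class ResectionEffect:
    """Set of surgery-affected edges plus the resected hemisphere.

    Edges are unordered node-label pairs; duplicates and orientation are
    normalized away on construction.
    """

    affected: set[tuple[str, str]]
    side: str

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown surgery side {self.side!r}")
        self.affected = {tuple(sorted(pair)) for pair in self.affected}

    @classmethod
    def from_pairs(cls, pairs, side: str) -> "ResectionEffect":
        return cls(affected={tuple(p) for p in pairs}, side=side)


def apply_resection(zn: ZNetwork, effect: ResectionEffect) -> ZNetwork:
    """Remove surgery-affected edges from a presurgery z-network.

    The returned network has kind ``"spared"``: its valid mask is the
    presurgery mask minus the affected pairs, z-values are unchanged on
    surviving edges, and the presurgical degrees are carried over so that
    abnormality percentages stay comparable before and after surgery.
    """
    if zn.kind != "presurgery":
        raise ValueError("resection applies to a presurgery network")
    index = {label: i for i, label in enumerate(zn.labels)}
    unknown = sorted({a for pair in effect.affected for a in pair} - index.keys())
    if unknown:
        raise ValueError(f"affected edges name unknown nodes: {unknown}")

    valid = zn.valid.copy()
    for a, b in effect.affected:
        i, j = index[a], index[b]
        valid[i, j] = False
        valid[j, i] = False
    z = np.where(valid, zn.z, np.nan)
    return ZNetwork(
        nodes=zn.nodes,
        z=z,
        valid=valid,
        degrees=zn.degrees.copy(),
        kind="spared",
        subject_id=zn.subject_id,
    )
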