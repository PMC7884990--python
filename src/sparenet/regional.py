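"""Regional localization of the surgical reduction in abnormality.

Nodes are relabeled ipsilateral/contralateral to each patient's surgery
and grouped into six areas per side (temporal, subcortical, parietal,
occipital, frontal, cingulate). For a patient group, the per-area
proportion of abnormal nodes is compared between the presurgery and
surgically spared networks (paired t-test across patients), and
whole-network load reductions are compared between outcome groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import AREAS
from .stats import StatResult, cohen_d, paired_t, ranksum_exact

SIDES = ("ipsi", "contra")


def relabel_ipsi_contra(nodes: pd.DataFrame, surgery_side: str) -> np.ndarray:
    """Per-node 'ipsi'/'contra' labels relative to the resected hemisphere."""
    if surgery_side not in ("left", "right"):
        raise ValueError(f"surgery_side must be 'left' or 'right', got {surgery_side!r}")
    hemi = nodes["hemisphere"]
    if hemi.isna().any():
        missing = nodes.loc[hemi.isna(), "label"].tolist()
        raise ValueError(f"nodes without hemisphere: {missing}")
    return np.where(hemi == surgery_side, "ipsi", "contra")


def _cell_matrix(
    abnormal_sets: list, nodes: pd.DataFrame, sides: list
) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient per-cell abnormal counts and cell ROI totals.

    Returns (counts, n_rois), each of shape (n_patients, 12); cells are
    ordered ipsi then contra, areas in canonical order.
    """
    n_pat = len(abnormal_sets)
    counts = np.zeros((n_pat, 12))
    n_rois = np.zeros((n_pat, 12))
    area = nodes["area"].to_numpy()
    for p, (abn, side) in enumerate(zip(abnormal_sets, sides)):
        rel = relabel_ipsi_contra(nodes, side)
        flags = np.zeros(len(nodes), dtype=bool)
        flags[np.asarray(list(abn), dtype=int)] = True
        for c, (s, a) in enumerate((s, a) for s in SIDES for a in AREAS):
            cell = (rel == s) & (area == a)
            n_rois[p, c] = cell.sum()
            counts[p, c] = flags[cell].sum()
    return counts, n_rois


def area_proportion_change(
    pre_sets: list,
    spared_sets: list,
    nodes: pd.DataFrame,
    sides: list,
) -> pd.DataFrame:
    """Group summary of the per-area drop in abnormal-node proportion.

    Parameters
    ----------
    pre_sets, spared_sets : list of abnormal-node index sets
        One per patient, computed at a fixed (tau_z, tau_p) on the
        presurgery and spared networks.
    nodes : node metadata table
    sides : surgery side per patient

    Returns
    -------
    DataFrame with one row per (side, area) cell: ROI count, group-mean
    proportions (with standard errors across patients) for both networks,
    the drop, and a paired t-test across patients on the per-patient
    proportions (p-values are BH-correctable downstream).
    """
    if not pre_sets:
        raise ValueError("empty patient group")
    if not (len(pre_sets) == len(spared_sets) == len(sides)):
        raise ValueError("pre/spared/side lists must align")
    pre_counts, n_rois = _cell_matrix(pre_sets, nodes, sides)
    spared_counts, _ = _cell_matrix(spared_sets, nodes, sides)
    with np.errstate(divide="ignore", invalid="ignore"):
        pre_prop = np.where(n_rois > 0, pre_counts / np.maximum(n_rois, 1), 0.0)
        spared_prop = np.where(n_rois > 0, spared_counts / np.maximum(n_rois, 1), 0.0)

    n_pat = len(pre_sets)
    rows = []
    for c, (s, a) in enumerate((s, a) for s in SIDES for a in AREAS):
        drop = pre_prop[:, c] - spared_prop[:, c]
        if n_pat >= 2 and drop.std(ddof=1) > 0:
            res = paired_t(pre_prop[:, c], spared_prop[:, c])
            t, p = res.statistic, res.pvalue
        else:
            t, p = np.nan, np.nan
        se = lambda v: v.std(ddof=1) / np.sqrt(n_pat) if n_pat >= 2 else np.nan
        rows.append(
            {
                "side": s,
                "area": a,
                "n_rois": n_rois[:, c].mean(),
                "pre_mean_abnormal": pre_counts[:, c].mean(),
                "spared_mean_abnormal": spared_counts[:, c].mean(),
                "pre_proportion": pre_prop[:, c].mean(),
                "spared_proportion": spared_prop[:, c].mean(),
                "se_pre": se(pre_prop[:, c]),
                "se_spared": se(spared_prop[:, c]),
                "drop": drop.mean(),
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def reduction_comparison(
    pre_loads,
    spared_loads,
    group_labels,
) -> dict:
    """Compare surgery-related load reductions between two outcome groups.

    Per patient: absolute reduction = pre - spared; proportional
    reduction = (pre - spared) / pre (0 when pre = 0 by convention).
    Group comparison: one-tailed exact rank-sum (group True > group
    False) and Cohen's d, for both measures.
    """
    pre = np.asarray(pre_loads, dtype=float)
    spared = np.asarray(spared_loads, dtype=float)
    labels = np.asarray(group_labels, dtype=bool)
    absolute = pre - spared
    with np.errstate(divide="ignore", invalid="ignore"):
        proportional = np.where(pre > 0, absolute / np.maximum(pre, 1e-300), 0.0)

    out = {}
    for name, values in (("absolute", absolute), ("proportional", proportional)):
        x, y = values[labels], values[~labels]
        res = ranksum_exact(x, y, alternative="greater")
        try:
            d = cohen_d(x, y)
        except ValueError:
            d = np.nan
        out[name] = StatResult(
            statistic=res.statistic,
            pvalue=res.pvalue,
            effect_size=d,
            method=res.method,
        )
        out[f"{name}_values"] = values
    return out
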