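"""Readers and writers for the cohort directory layout.

All formats are plain text: connectivity matrices as TSV with node labels
on both axes, affected-edge lists as two-column TSV, node metadata as
TSV, clinical/outcome tables as CSV, and ground truth as JSON. Unordered
edges are stored with the lexicographically smaller label first.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .network import Connectome, ZNetwork
from .resection import ResectionEffect


def write_matrix(path, matrix: np.ndarray, labels: list) -> None:
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path) -> tuple[list, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [str(x) for x in df.index]
    if labels != [str(c) for c in df.columns]:
        raise ValueError(f"{path}: row and column labels differ")
    return labels, df.to_numpy(dtype=float)


def read_connectome(gfa_path, streamline_path, nodes: pd.DataFrame,
                    subject_id: str = "", atol: float = 1e-9) -> Connectome:
    """Read a subject's gFA and streamline matrices against a node table.

    Near-symmetric matrices (within ``atol``) are symmetrized by
    averaging with the transpose; larger asymmetries are an error, as are
    dimension mismatches and gFA values outside (0, 1).
    """
    labels_g, gfa = read_matrix(gfa_path)
    labels_s, streamlines = read_matrix(streamline_path)
    expected = nodes["label"].tolist()
    if labels_g != expected or labels_s != expected:
        raise ValueError(f"{gfa_path}: node ordering does not match metadata table")
    if gfa.shape[0] != gfa.shape[1] or gfa.shape != streamlines.shape:
        raise ValueError(f"{gfa_path}: matrices must be square and matching")
    for name, m in (("gfa", gfa), ("streamline", streamlines)):
        asym = np.nanmax(np.abs(m - m.T)) if m.size else 0.0
        if not (np.isnan(asym) or asym <= atol):
            raise ValueError(f"{gfa_path}: {name} matrix asymmetry {asym} exceeds {atol}")
    gfa = (gfa + gfa.T) / 2.0
    streamlines = np.rint((streamlines + streamlines.T) / 2.0).astype(int)
    return Connectome(nodes=nodes, streamlines=streamlines, gfa=gfa,
                      subject_id=subject_id)


def write_connectome(directory, conn: Connectome) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = conn.subject_id or "subject"
    gfa = np.where(np.isfinite(conn.gfa), conn.gfa, np.nan)
    write_matrix(directory / f"{sid}.gfa.tsv", gfa, conn.labels)
    write_matrix(directory / f"{sid}.streamline.tsv", conn.streamlines, conn.labels)


def write_affected_edges(path, effect: ResectionEffect) -> None:
    rows = sorted(effect.affected)
    with open(path, "w") as fh:
        fh.write(f"# side={effect.side}\n")
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def read_affected_edges(path) -> ResectionEffect:
    side = None
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "side=" in line:
                    side = line.split("side=")[1].strip()
                continue
            a, b = line.split("\t")
            pairs.append((a, b))
    if side is None:
        raise ValueError(f"{path}: missing '# side=' header line")
    return ResectionEffect.from_pairs(pairs, side=side)


def write_znetwork(path_prefix, zn: ZNetwork) -> None:
    z = np.where(zn.valid, zn.z, np.nan)
    write_matrix(f"{path_prefix}.z.tsv", z, zn.labels)
    write_matrix(f"{path_prefix}.mask.tsv", zn.valid.astype(int), zn.labels)
    meta = {"kind": zn.kind, "subject_id": zn.subject_id,
            "degrees": zn.degrees.tolist()}
    Path(f"{path_prefix}.meta.json").write_text(json.dumps(meta))


def read_znetwork(path_prefix, nodes: pd.DataFrame) -> ZNetwork:
    labels, z = read_matrix(f"{path_prefix}.z.tsv")
    _, mask = read_matrix(f"{path_prefix}.mask.tsv")
    meta = json.loads(Path(f"{path_prefix}.meta.json").read_text())
    return ZNetwork(nodes=nodes, z=z, valid=mask.astype(bool),
                    degrees=np.array(meta["degrees"], dtype=int),
                    kind=meta["kind"], subject_id=meta["subject_id"])


# ---------------------------------------------------------------------------
# Cohort directory


def write_cohort(cohort, out_dir) -> None:
    """Write a synthetic cohort to the standard directory layout."""
    out = Path(out_dir)
    (out / "controls").mkdir(parents=True, exist_ok=True)
    (out / "patients").mkdir(parents=True, exist_ok=True)
    cohort.nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
    for c in cohort.controls:
        write_connectome(out / "controls", c)
    for p, eff in zip(cohort.patients, cohort.effects):
        write_connectome(out / "patients", p)
        write_affected_edges(out / "patients" / f"{p.subject_id}.affected_edges.tsv", eff)
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.outcomes.to_csv(out / "outcomes.csv", index=False)
    truth = [
        {
            "patient_id": t.patient_id,
            "planted_nodes": list(t.planted_nodes),
            "planted_edges": sorted(list(e) for e in t.planted_edges),
            "true_pre_load": t.true_pre_load,
            "true_spared_load": t.true_spared_load,
            "latent_score": t.latent_score,
        }
        for t in cohort.truths
    ]
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))


class CohortOnDisk:
    """Lazy view of a cohort directory with manifest validation."""

    def __init__(self, directory):
        self.dir = Path(directory)
        self.nodes = pd.read_csv(self.dir / "nodes.tsv", sep="\t")
        self.clinical = pd.read_csv(self.dir / "clinical.csv")
        self.outcomes = pd.read_csv(self.dir / "outcomes.csv")
        self.control_ids = sorted(
            p.name.removesuffix(".gfa.tsv")
            for p in (self.dir / "controls").glob("*.gfa.tsv")
        )
        self.patient_ids = sorted(
            p.name.removesuffix(".gfa.tsv")
            for p in (self.dir / "patients").glob("*.gfa.tsv")
        )
        self._validate()

    def _validate(self) -> None:
        ids = self.control_ids + self.patient_ids
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate subject ids in cohort directory")
        for pid in self.patient_ids:
            for suffix in (".streamline.tsv", ".affected_edges.tsv"):
                path = self.dir / "patients" / f"{pid}{suffix}"
                if not path.exists():
                    raise FileNotFoundError(f"missing {path} for patient {pid}")
        missing = set(self.patient_ids) - set(self.clinical["patient_id"])
        if missing:
            raise ValueError(f"patients without clinical rows: {sorted(missing)}")

    def control(self, cid: str) -> Connectome:
        d = self.dir / "controls"
        return read_connectome(d / f"{cid}.gfa.tsv", d / f"{cid}.streamline.tsv",
                               self.nodes, subject_id=cid)

    def patient(self, pid: str) -> Connectome:
        d = self.dir / "patients"
        return read_connectome(d / f"{pid}.gfa.tsv", d / f"{pid}.streamline.tsv",
                               self.nodes, subject_id=pid)

    def effect(self, pid: str) -> ResectionEffect:
        return read_affected_edges(self.dir / "patients" / f"{pid}.affected_edges.tsv")

    def controls(self) -> list:
        return [self.control(cid) for cid in self.control_ids]
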