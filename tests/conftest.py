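import numpy as np
import pandas as pd
import pytest

from sparenet import Connectome, ZNetwork
from sparenet.network import AREAS


def toy_nodes(n: int) -> pd.DataFrame:
    """Balanced two-hemisphere node table for tests."""
    half = n // 2
    rows = []
    for hemi, prefix in (("left", "L"), ("right", "R")):
        for i in range(half):
            rows.append((f"{prefix}{i + 1:03d}", hemi, AREAS[i % len(AREAS)]))
    return pd.DataFrame(rows, columns=["label", "hemisphere", "area"])


def make_connectome(gfa_upper: dict, n: int, subject_id: str = "s") -> Connectome:
    """Connectome from a dict {(i, j): gfa} of upper-triangle edges."""
    gfa = np.full((n, n), np.nan)
    s = np.zeros((n, n), dtype=int)
    for (i, j), w in gfa_upper.items():
        gfa[i, j] = gfa[j, i] = w
        s[i, j] = s[j, i] = 5
    return Connectome(nodes=toy_nodes(n), streamlines=s, gfa=gfa, subject_id=subject_id)


def random_znetwork(rng: np.random.Generator, n: int = 20,
                    density: float = 0.5, scale: float = 2.0) -> ZNetwork:
    upper = np.triu(rng.random((n, n)) < density, 1)
    valid = upper | upper.T
    z = np.full((n, n), np.nan)
    vals = rng.normal(0, scale, size=int(upper.sum()))
    z[np.where(upper)] = vals
    z[np.where(upper.T[::1])] = z.T[np.where(upper.T[::1])]
    z = np.where(valid, np.where(np.isnan(z), z.T, z), np.nan)
    return ZNetwork(nodes=toy_nodes(n), z=z, valid=valid,
                    degrees=valid.sum(axis=1), kind="presurgery")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by integration tests.

    The planted-node count and outcome coefficients are rescaled to the
    smaller parcellation so that true spared loads stay in the localized
    regime and all ILAE classes appear.
    """
    from sparenet import GeneratorConfig, generate_cohort
    from sparenet.synthetic import OutcomeCoefs

    cfg = GeneratorConfig(
        n_nodes=40, n_controls=15, n_patients=18,
        planted_nodes_per_patient=3,
        outcome_coefs=OutcomeCoefs(intercept=-2.5, spared_load=1.5),
        seed=77,
    )
    return generate_cohort(cfg)
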