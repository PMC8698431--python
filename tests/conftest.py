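import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gtdmeth.config import SimulationConfig
from gtdmeth.integration import SUBSET_LABELS

settings.register_profile(
    "repro", deadline=None, derandomize=True, suppress_health_check=list(HealthCheck)
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-size simulation shared by fast tests."""
    return SimulationConfig(n_probes=4000, n_genes=400, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    from gtdmeth.simulate import generate_beta, generate_gene_annotation, generate_manifest

    manifest = generate_manifest(small_cfg)
    bm, planting = generate_beta(small_cfg, manifest, return_planting=True)
    annot = generate_gene_annotation(small_cfg, manifest)
    return manifest, bm, planting, annot


@pytest.fixture(scope="session")
def published_subset_counts():
    """The 12-subset gene counts of the integrative GTD study's summary
    table (all genes plus imprinted / PPE / TBDE annotation columns)."""
    data = {
        "M&C DM/UR": (1, 0, 0, 0),
        "M&C UM/DR": (34, 0, 7, 20),
        "M DM/UR": (405, 4, 1, 31),
        "C DM/UR": (17, 0, 0, 9),
        "M UM/DR": (307, 4, 10, 86),
        "C UM/DR": (714, 12, 59, 236),
        "M&C DM/DR": (0, 0, 0, 0),
        "M&C UM/UR": (9, 1, 0, 4),
        "M DM/DR": (111, 3, 4, 22),
        "M UM/UR": (723, 9, 6, 73),
        "C DM/DR": (25, 0, 0, 12),
        "C UM/UR": (298, 4, 0, 91),
    }
    df = pd.DataFrame.from_dict(
        data, orient="index", columns=["n_genes", "imprinted", "ppe", "tbde"]
    )
    return df.loc[list(SUBSET_LABELS)]


def brute_force_ward(X: np.ndarray) -> np.ndarray:
    """O(n^3) Ward.D2 agglomeration via the Lance–Williams update, in scipy
    linkage format. Independent oracle for cluster_samples."""
    n = X.shape[0]
    D = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(np.linalg.norm(X[i] - X[j]))

    def dist(a, b):
        return D[(min(a, b), max(a, b))]

    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    Z = []
    nxt = n
    while len(active) > 1:
        best = min(
            (
                (dist(a, b), a, b)
                for idx, a in enumerate(active)
                for b in active[idx + 1 :]
            ),
            key=lambda t: (t[0], t[1], t[2]),
        )
        dij, i, j = best
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            d2 = (
                (ni + nk) * dist(i, k) ** 2
                + (nj + nk) * dist(j, k) ** 2
                - nk * dij**2
            ) / (ni + nj + nk)
            D[(min(nxt, k), max(nxt, k))] = float(np.sqrt(max(d2, 0.0)))
        Z.append([float(i), float(j), dij, float(ni + nj)])
        sizes[nxt] = ni + nj
        active.remove(i)
        active.remove(j)
        active.append(nxt)
        nxt += 1
    return np.asarray(Z)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Sort, scale, cumulative-min BH oracle."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
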