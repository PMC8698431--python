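"""Core methylation containers and operations.

β-values (methylated signal fraction, in [0,1]) are the interpretable scale;
M-values, the logit2 transform log2(β/(1−β)), are the homoscedastic scale
used for statistical testing. This module holds the probes × samples matrix
container, the β/M conversions, per-tissue medians, Ward.D2 hierarchical
clustering of samples, and the parent-of-origin imprint-class summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .config import GROUPS, IMPRINT_CLASSES

DEFAULT_EPS = 1e-6


@dataclass
class BetaMatrix:
    """Probes × samples β-value matrix with a sample → group map."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.hasnans or v.columns.hasnans:
            raise ValueError("probe and sample identifiers must not be missing")
        if not v.index.is_unique or not v.columns.is_unique:
            raise ValueError("probe and sample identifiers must be unique")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any() or arr.min() < 0.0 or arr.max() > 1.0:
            raise ValueError("beta values must lie in [0,1] with no missing entries")
        missing = [s for s in v.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        self.groups = self.groups.reindex(v.columns)

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group: str) -> List[str]:
        if group not in set(self.groups):
            raise KeyError(f"unknown group label {group!r}")
        return list(self.groups.index[self.groups == group])


def beta_to_m(beta, eps: float = DEFAULT_EPS):
    """logit2 transform, clipping β into [eps, 1−eps] so M stays finite."""
    if not (0.0 < eps < 0.5):
        raise ValueError("eps must lie in (0, 0.5)")
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse logit2: β = 2^M / (1 + 2^M)."""
    p = np.exp2(np.asarray(m, dtype=float))
    out = p / (1.0 + p)
    return out if out.ndim else float(out)


def m_matrix(bm: BetaMatrix, eps: float = DEFAULT_EPS) -> pd.DataFrame:
    """M-value matrix of the same shape as the β matrix."""
    return pd.DataFrame(
        beta_to_m(bm.values.to_numpy(), eps), index=bm.probe_ids, columns=bm.sample_ids
    )


def probe_group_medians(bm: BetaMatrix, group: str) -> pd.Series:
    """Per-probe median β across the samples of one group."""
    cols = bm.samples_in(group)
    return bm.values[cols].median(axis=1)


def group_median_beta(bm: BetaMatrix, group: str) -> float:
    """Global per-tissue methylation level.

    Defined as the median across probes of the per-probe median across the
    group's samples (robust to unbalanced group sizes).
    """
    return float(probe_group_medians(bm, group).median())


def group_medians(bm: BetaMatrix) -> Dict[str, float]:
    return {g: group_median_beta(bm, g) for g in pd.unique(bm.groups)}


@dataclass
class ClusterResult:
    """Ward.D2 agglomeration of samples on Euclidean β distances."""

    linkage: np.ndarray  # scipy linkage record (merge order + heights)
    leaf_order: List[str]
    purity: Dict[str, float]  # per-group clade purity in [0,1]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _clade_purity(Z: np.ndarray, labels: Sequence[str]) -> Dict[str, float]:
    """Fraction of each group's samples inside its largest pure subtree.

    Purity 1 means the group's samples form a complete clade of their own.
    """
    n = len(labels)
    leafsets: List[frozenset] = [frozenset([i]) for i in range(n)]
    for a, b, _, _ in Z:
        leafsets.append(leafsets[int(a)] | leafsets[int(b)])
    by_group: Dict[str, set] = {}
    for i, g in enumerate(labels):
        by_group.setdefault(g, set()).add(i)
    purity = {}
    for g, members in by_group.items():
        best = 1  # singleton leaves are always pure
        for ls in leafsets:
            if ls <= members and len(ls) > best:
                best = len(ls)
        purity[g] = best / len(members)
    return purity


def cluster_samples(bm: BetaMatrix) -> ClusterResult:
    """Hierarchical clustering of samples on all probes.

    Euclidean distances between β-value columns, Ward.D2 agglomeration
    (the Murtagh–Legendre squared-distance update used by scipy's ``ward``
    on raw observations). Ties are resolved by scipy's lowest-index rule.
    """
    if bm.values.shape[1] < 2:
        raise ValueError("clustering requires at least two samples")
    X = bm.values.to_numpy(dtype=float).T
    Z = hierarchy.linkage(X, method="ward")
    order = hierarchy.leaves_list(Z)
    labels = [str(bm.groups.loc[s]) for s in bm.sample_ids]
    return ClusterResult(
        linkage=Z,
        leaf_order=[bm.sample_ids[i] for i in order],
        purity=_clade_purity(Z, labels),
    )


@dataclass
class ImprintDistribution:
    """Per-group β summaries for one imprint class of probes."""

    imprint_class: str
    n_probes: int
    summary: pd.DataFrame = field(default=None)  # rows: group; cols: median, q1, q3
    empty: bool = False

    def median(self, group: str) -> float:
        if self.empty:
            raise ValueError(f"imprint class {self.imprint_class!r} has no probes")
        return float(self.summary.loc[group, "median"])


def imprint_distributions(
    bm: BetaMatrix,
    annot: pd.DataFrame,
    classes: Sequence[str] = IMPRINT_CLASSES,
    groups: Optional[Sequence[str]] = None,
) -> List[ImprintDistribution]:
    """β distribution summaries restricted to maternal / paternal imprint probes.

    An empty imprint class yields an explicit empty-result marker rather than
    a silent zero-filled summary.
    """
    if "IMPRINT" not in annot.columns:
        raise ValueError("annotation must carry an IMPRINT column")
    if groups is None:
        groups = [g for g in GROUPS if g in set(bm.groups)]
    out: List[ImprintDistribution] = []
    for cls in classes:
        probes = annot.index[annot["IMPRINT"] == cls].intersection(bm.probe_ids)
        if len(probes) == 0:
            warnings.warn(f"imprint class {cls!r} has no probes in the matrix")
            out.append(ImprintDistribution(imprint_class=cls, n_probes=0, empty=True))
            continue
        sub = bm.values.loc[probes]
        rows = {}
        for g in groups:
            vals = sub[bm.samples_in(g)].to_numpy().ravel()
            rows[g] = {
                "median": float(np.median(vals)),
                "q1": float(np.quantile(vals, 0.25)),
                "q3": float(np.quantile(vals, 0.75)),
            }
        out.append(
            ImprintDistribution(
                imprint_class=cls,
                n_probes=len(probes),
                summary=pd.DataFrame.from_dict(rows, orient="index"),
            )
        )
    return out
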