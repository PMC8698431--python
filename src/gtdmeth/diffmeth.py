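"""Per-probe differential methylation testing and its gene-level aggregation.

Two testing routes are provided, mirroring the two analyses a 450K study
typically runs:

* a pairwise route (``dm_ttest_contrast``) using Student's or Welch's t-test
  on M-values per probe, routed by an F-test for equality of variances, with
  q < 0.1 flagging significance — this feeds the methylation–expression
  integration;
* a moderated route (``dm_moderated``) using an in-house limma-style
  empirical-Bayes variance shrinkage across the probe ensemble, with
  q < 0.05 — this feeds the Δβ-category counting across all four groups.

Δβ is always the difference of per-probe group *median* β-values
(target − reference); |Δβ| bins define the mild / moderate / strong
categories and the hyper / hypo direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

from .config import CONTRASTS
from .core import BetaMatrix, DEFAULT_EPS, m_matrix, probe_group_medians

# |Δβ| category bins: none ≤ 0.125 < mild ≤ 0.25 < moderate ≤ 0.5 < strong
DELTA_BETA_BINS: Tuple[float, float, float] = (0.125, 0.25, 0.5)
DEFAULT_ALPHA_F = 0.05
Q_TTEST = 0.10
Q_MODERATED = 0.05


def categorize_delta_beta(delta_beta: float) -> Tuple[str, str]:
    """Category (none/mild/moderate/strong) and direction (hyper/hypo/none).

    The lower boundary is strict: |Δβ| exactly 0.125 is 'none'.
    """
    if not -1.0 <= delta_beta <= 1.0:
        raise ValueError("delta_beta must lie in [-1, 1]")
    a = abs(delta_beta)
    lo, mid, hi = DELTA_BETA_BINS
    if a <= lo:
        return "none", "none"
    direction = "hyper" if delta_beta > 0 else "hypo"
    if a <= mid:
        return "mild", direction
    if a <= hi:
        return "moderate", direction
    return "strong", direction


def _categorize_vec(delta_beta: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    a = np.abs(delta_beta)
    lo, mid, hi = DELTA_BETA_BINS
    category = np.full(a.shape, "none", dtype=object)
    category[(a > lo) & (a <= mid)] = "mild"
    category[(a > mid) & (a <= hi)] = "moderate"
    category[a > hi] = "strong"
    direction = np.full(a.shape, "none", dtype=object)
    direction[(a > lo) & (delta_beta > 0)] = "hyper"
    direction[(a > lo) & (delta_beta < 0)] = "hypo"
    return category, direction


def bh_qvalues(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# pairwise t-test route
# ---------------------------------------------------------------------------

def dm_test_probe(
    x: Sequence[float], y: Sequence[float], alpha_f: float = DEFAULT_ALPHA_F
) -> Tuple[float, float, str]:
    """Student's or Welch's t-test on one probe's M-values, F-test routed.

    A two-sided F-test on the variance ratio at level ``alpha_f`` decides the
    route: pooled-variance Student t when equality is not rejected, Welch t
    with Satterthwaite degrees of freedom otherwise. Returns
    (t statistic, two-sided p, route).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        # degenerate: no within-group variability at all
        if x.mean() == y.mean():
            return 0.0, 1.0, "student"
        return np.inf if x.mean() > y.mean() else -np.inf, 0.0, "degenerate"
    if vx == 0.0 or vy == 0.0:
        route = "welch"
    else:
        f = vx / vy
        pf = 2.0 * min(
            stats.f.cdf(f, x.size - 1, y.size - 1),
            stats.f.sf(f, x.size - 1, y.size - 1),
        )
        route = "student" if pf >= alpha_f else "welch"
    t, p = stats.ttest_ind(x, y, equal_var=(route == "student"))
    return float(t), float(p), route


def _ttest_arrays(
    X: np.ndarray, Y: np.ndarray, alpha_f: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized F-routed t-test over probes (rows)."""
    nx, ny = X.shape[1], Y.shape[1]
    mx, my = X.mean(axis=1), Y.mean(axis=1)
    vx, vy = X.var(axis=1, ddof=1), Y.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        f = vx / vy
        pf = 2.0 * np.minimum(stats.f.cdf(f, nx - 1, ny - 1), stats.f.sf(f, nx - 1, ny - 1))
    one_zero = ((vx == 0.0) ^ (vy == 0.0))
    both_zero = (vx == 0.0) & (vy == 0.0)
    student = (pf >= alpha_f) & ~one_zero & ~both_zero

    t = np.zeros(X.shape[0])
    p = np.ones(X.shape[0])
    route = np.where(student, "student", "welch").astype(object)

    # pooled-variance Student
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_s = (mx - my) / np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        p_s = 2.0 * stats.t.sf(np.abs(t_s), nx + ny - 2)
        # Welch with Satterthwaite df
        se2 = vx / nx + vy / ny
        t_w = (mx - my) / np.sqrt(se2)
        df_w = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        p_w = 2.0 * stats.t.sf(np.abs(t_w), df_w)

    t = np.where(student, t_s, t_w)
    p = np.where(student, p_s, p_w)

    # degenerate rows: both variances zero
    eq = both_zero & (mx == my)
    ne = both_zero & (mx != my)
    t[eq], p[eq] = 0.0, 1.0
    route[eq] = "student"
    t[ne] = np.where(mx[ne] > my[ne], np.inf, -np.inf)
    p[ne] = 0.0
    route[ne] = "degenerate"
    return t, p, route


def dm_ttest_contrast(
    bm: BetaMatrix,
    contrast: str,
    alpha_f: float = DEFAULT_ALPHA_F,
    eps: float = DEFAULT_EPS,
    q_threshold: float = Q_TTEST,
) -> pd.DataFrame:
    """Per-probe DM results for one contrast via the F-routed t-test on M-values.

    Columns: probe, contrast, delta_beta, delta_m, t, p, q, route, category,
    direction, significant (q < ``q_threshold``).
    """
    target, ref = CONTRASTS[contrast]
    M = m_matrix(bm, eps)
    X = M[bm.samples_in(target)].to_numpy()
    Y = M[bm.samples_in(ref)].to_numpy()
    t, p, route = _ttest_arrays(X, Y, alpha_f)
    delta_beta = (probe_group_medians(bm, target) - probe_group_medians(bm, ref)).to_numpy()
    delta_m = X.mean(axis=1) - Y.mean(axis=1)
    q = bh_qvalues(p)
    category, direction = _categorize_vec(delta_beta)
    return pd.DataFrame(
        {
            "probe": bm.probe_ids,
            "contrast": contrast,
            "delta_beta": delta_beta,
            "delta_m": delta_m,
            "t": t,
            "p": p,
            "q": q,
            "route": route,
            "category": category,
            "direction": direction,
            "significant": q < q_threshold,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# moderated (empirical Bayes) route
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (limma's recipe)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_prior_variance(s2: np.ndarray, df: int) -> Tuple[float, float]:
    """Method-of-moments fit of the inverse-chi-square variance prior.

    Under the hierarchical model, z = log s² has variance
    trigamma(df/2) + trigamma(d0/2) and a mean offset involving digamma
    terms; matching the empirical moments of z yields (d0, s0²).
    d0 = inf (no excess dispersion) collapses every probe to s0².
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(s2[ok])
    zbar, zvar = z.mean(), z.var(ddof=1)
    excess = zvar - polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(zbar - (digamma(df / 2.0) - np.log(df / 2.0))))
    else:
        d0 = 2.0 * _trigamma_inverse(float(excess))
        s0_2 = float(
            np.exp(
                zbar
                - (digamma(df / 2.0) - np.log(df / 2.0))
                + (digamma(d0 / 2.0) - np.log(d0 / 2.0))
            )
        )
    return d0, s0_2


def moderated_variance(s2: np.ndarray, df: int, d0: float, s0_2: float) -> np.ndarray:
    """Posterior variance s̃² = (d0·s0² + df·s²) / (d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(d0):
        return np.full_like(s2, s0_2)
    return (d0 * s0_2 + df * s2) / (d0 + df)


def dm_moderated(
    bm: BetaMatrix,
    contrast: str,
    eps: float = DEFAULT_EPS,
    q_threshold: float = Q_MODERATED,
    d0_override: Optional[float] = None,
) -> pd.DataFrame:
    """Per-probe moderated-t DM results for one contrast.

    A one-way group-means model is fit per probe over all sample groups;
    residual variances are shrunk towards an empirical-Bayes prior estimated
    across the probe ensemble, and the contrast (target − reference of group
    mean M) is tested on d + d0 degrees of freedom. ``d0_override=0``
    reproduces the ordinary unmoderated t.
    """
    target, ref = CONTRASTS[contrast]
    M = m_matrix(bm, eps)
    if M.shape[0] < 50:
        raise ValueError("moderated testing needs >=50 probes to estimate the prior")
    groups = [g for g in pd.unique(bm.groups)]
    cols_by_group = {g: bm.samples_in(g) for g in groups}
    n_total = sum(len(c) for c in cols_by_group.values())
    df_resid = n_total - len(groups)
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    for g in (target, ref):
        if len(cols_by_group[g]) < 2:
            raise ValueError(f"group {g!r} needs >=2 samples")

    A = M.to_numpy()
    rss = np.zeros(A.shape[0])
    means: Dict[str, np.ndarray] = {}
    for g, cols in cols_by_group.items():
        sub = M[cols].to_numpy()
        mu = sub.mean(axis=1)
        means[g] = mu
        rss += ((sub - mu[:, None]) ** 2).sum(axis=1)
    s2 = rss / df_resid

    if d0_override is not None and d0_override == 0:
        d0 = 0.0  # no-shrinkage limit: ordinary t
        s2_tilde = s2.copy()
    else:
        d0, s0_2 = estimate_prior_variance(s2, df_resid)
        if d0_override is not None:
            d0 = float(d0_override)
        s2_tilde = moderated_variance(s2, df_resid, d0, s0_2)

    nt, nr = len(cols_by_group[target]), len(cols_by_group[ref])
    delta_m = means[target] - means[ref]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta_m / np.sqrt(s2_tilde * (1.0 / nt + 1.0 / nr))
    t = np.where(np.isnan(t), 0.0, t)  # zero effect over zero variance
    df_total = df_resid + (0.0 if np.isinf(d0) else d0)
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)

    delta_beta = (probe_group_medians(bm, target) - probe_group_medians(bm, ref)).to_numpy()
    q = bh_qvalues(p)
    category, direction = _categorize_vec(delta_beta)
    return pd.DataFrame(
        {
            "probe": bm.probe_ids,
            "contrast": contrast,
            "delta_beta": delta_beta,
            "delta_m": delta_m,
            "t": t,
            "p": p,
            "q": q,
            "route": "moderated",
            "category": category,
            "direction": direction,
            "significant": q < q_threshold,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene-level calls
# ---------------------------------------------------------------------------

def call_genes(
    dm: pd.DataFrame,
    annot: pd.DataFrame,
    min_abs_delta_beta: float = DELTA_BETA_BINS[0],
    q_threshold: float = Q_TTEST,
) -> pd.DataFrame:
    """Gene-level methylation calls from per-probe DM results.

    A probe qualifies when it is significant (q below threshold) AND
    |Δβ| exceeds ``min_abs_delta_beta`` (strict). A gene is hyper- or
    hypomethylated if any of its qualifying probes is, *ambiguous* when it
    has qualifying probes in both directions (such genes must be excluded
    downstream), and *none* otherwise. Probes mapping to several genes
    contribute to each; unannotated probes are ignored.

    Returns columns: gene, contrast, call, max_abs_delta_beta, n_probes.
    """
    from .simulate import manifest_gene_map  # local import to avoid a cycle

    links = manifest_gene_map(annot)
    merged = dm.merge(links, on="probe", how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["gene", "contrast", "call", "max_abs_delta_beta", "n_probes"])
    contrast = dm["contrast"].iloc[0]
    merged["qualifying"] = (
        (merged["q"] < q_threshold) & (merged["delta_beta"].abs() > min_abs_delta_beta)
    )
    merged["is_hyper"] = merged["qualifying"] & (merged["delta_beta"] > 0)
    merged["is_hypo"] = merged["qualifying"] & (merged["delta_beta"] < 0)
    g = merged.groupby("gene").agg(
        any_hyper=("is_hyper", "any"),
        any_hypo=("is_hypo", "any"),
        max_abs_delta_beta=("delta_beta", lambda s: float(np.max(np.abs(s)))),
        n_probes=("probe", "nunique"),
    )
    call = np.select(
        [g["any_hyper"] & g["any_hypo"], g["any_hyper"], g["any_hypo"]],
        ["ambiguous", "hyper", "hypo"],
        default="none",
    )
    out = g.reset_index()[["gene", "max_abs_delta_beta", "n_probes"]]
    out.insert(1, "contrast", contrast)
    out.insert(2, "call", call)
    return out


# ---------------------------------------------------------------------------
# TSS-distance profiles
# ---------------------------------------------------------------------------

@dataclass
class TssProfile:
    """Frequency of direction-matching DM probes per TSS-distance bin."""

    contrast: str
    direction: str
    bin_edges: np.ndarray
    counts: np.ndarray
    total_in_window: int
    frequencies: Optional[np.ndarray]  # None when the window is empty
    scatter: pd.DataFrame  # (probe, distance, delta_m, direction) within 5 kbp


def tss_profile(
    dm: pd.DataFrame,
    annot: pd.DataFrame,
    direction: str,
    window: int = 1000,
    bin_width: int = 100,
    scatter_max: int = 5000,
) -> TssProfile:
    """DM frequency as a function of distance to the nearest TSS.

    The [0, window) interval is partitioned into ``window/bin_width``
    segments; each bin's frequency is the count of DM probes of the stated
    direction in the bin divided by the total number of probes within the
    window. Also returns the (distance, ΔM) scatter records within 5 kbp.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    d = dm.merge(annot[["DIST_TSS"]], left_on="probe", right_index=True, how="inner")
    in_window = d[d["DIST_TSS"] < window]
    edges = np.arange(0, window + bin_width, bin_width)
    total = len(in_window)
    sig = in_window[in_window["significant"] & (in_window["direction"] == direction)]
    counts, _ = np.histogram(sig["DIST_TSS"], bins=edges)
    freqs = counts / total if total > 0 else None
    sc = d[d["DIST_TSS"] <= scatter_max]
    scatter = sc[["probe", "DIST_TSS", "delta_m", "direction"]].rename(
        columns={"DIST_TSS": "distance"}
    )
    return TssProfile(
        contrast=dm["contrast"].iloc[0] if len(dm) else "",
        direction=direction,
        bin_edges=edges,
        counts=counts,
        total_in_window=total,
        frequencies=freqs,
        scatter=scatter.reset_index(drop=True),
    )
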