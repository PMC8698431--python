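"""Synthetic 450K-style dataset generator.

Generates probe manifests, β-value matrices, differential-expression tables,
gene annotations, gene sets, and tissue-microarray immunoscore tables with
the planted statistical structure the downstream analysis assumes:

* four sample groups with escalating global methylation medians
  (VT < PLA < MOLE < CC by default),
* maternal / paternal imprint marks with group-specific asymmetries
  (maternal highest in moles; paternal lowest in moles, highest in
  choriocarcinoma),
* differentially methylated probes planted in three Δβ magnitude tiers
  against the contrast actually analysed downstream,
* DE tables whose thresholds select exactly the planted gene set, with
  configurable direction bias and methylation–expression coupling.

Per-probe noise is Beta-distributed around a probe center: centers come from
a bimodal logit-normal mixture (mimicking 450K bimodality) shifted per group
in logit space; the shift is calibrated by bisection so the median of the
final probe centers equals the configured group median exactly.
"""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .config import (
    CONTRASTS,
    DE_THRESHOLDS,
    GROUPS,
    IMPRINT_CLASSES,
    PATHOLOGICAL_GROUPS,
    PLANT_CONTRAST,
    SimulationConfig,
)
from .core import BetaMatrix
from .integration import DETable

_CATEGORIES = ("mild", "moderate", "strong")
# margin keeping planted Beta centers away from the support boundary
_CENTER_MARGIN = 0.01

# substream tags so regenerating one table does not disturb the others
_STREAMS = {"manifest": 1, "beta": 2, "expression": 3, "immuno": 4, "annotation": 5, "genesets": 6}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def _logit2(b):
    b = np.asarray(b, dtype=float)
    return np.log2(b / (1.0 - b))


def _expit2(x):
    p = np.exp2(np.asarray(x, dtype=float))
    return p / (1.0 + p)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sample_tss_distances(rng: np.random.Generator, n: int, model: Mapping[str, float]) -> np.ndarray:
    """Distances to nearest TSS: point mass near the promoter plus an
    exponential tail truncated at ``max_distance``."""
    p = float(model["p_proximal"])
    pm = float(model["proximal_max"])
    scale = float(model["tail_scale"])
    dmax = float(model["max_distance"])
    proximal = rng.random(n) < p
    d = np.empty(n)
    d[proximal] = rng.uniform(0.0, pm, proximal.sum())
    n_tail = (~proximal).sum()
    # inverse-CDF draw from an exponential truncated to [pm, dmax]
    u = rng.random(n_tail)
    span = 1.0 - np.exp(-(dmax - pm) / scale)
    d[~proximal] = pm - scale * np.log1p(-u * span)
    return np.round(d).astype(int)


def generate_manifest(cfg: SimulationConfig) -> pd.DataFrame:
    """Probe manifest: genomic position, gene links, TSS distance, imprint class.

    Each gene receives 1–15 probes (uniform); a small fraction of probes
    carry a second gene symbol, joined with ';' in the Illumina dialect.
    Leftover probes are intergenic (empty gene field). Imprint classes are
    disjoint Bernoulli-sampled probe subsets.
    """
    cfg.validate()
    if cfg.n_probes < 8 * cfg.n_genes:
        raise ValueError(
            "n_probes must be at least 8x n_genes to satisfy the 1-15 "
            "probes-per-gene coverage model"
        )
    rng = _rng(cfg.seed, "manifest")
    probe_ids = [f"cg{i:08d}" for i in range(1, cfg.n_probes + 1)]
    genes = [f"GENE{i:05d}" for i in range(1, cfg.n_genes + 1)]

    counts = rng.integers(1, 16, size=cfg.n_genes)
    if counts.sum() > cfg.n_probes:
        raise ValueError("gene probe demand exceeds n_probes; increase n_probes")
    pool = rng.permutation(cfg.n_probes)
    gene_of = np.full(cfg.n_probes, "", dtype=object)
    pos = 0
    for gi, c in enumerate(counts):
        for p in pool[pos : pos + c]:
            gene_of[p] = genes[gi]
        pos += c

    # ~5% of gene-linked probes pick up a second symbol
    linked = np.flatnonzero(gene_of != "")
    second = linked[rng.random(linked.size) < 0.05]
    for p in second:
        other = genes[rng.integers(0, cfg.n_genes)]
        if other != gene_of[p]:
            gene_of[p] = f"{gene_of[p]};{other}"

    u = rng.random(cfg.n_probes)
    imprint = np.full(cfg.n_probes, "", dtype=object)
    imprint[u < cfg.frac_imprinted_maternal] = "maternal"
    imprint[
        (u >= cfg.frac_imprinted_maternal)
        & (u < cfg.frac_imprinted_maternal + cfg.frac_imprinted_paternal)
    ] = "paternal"

    manifest = pd.DataFrame(
        {
            "CHR": rng.integers(1, 23, size=cfg.n_probes).astype(str),
            "MAPINFO": rng.integers(10_000, 250_000_000, size=cfg.n_probes),
            "UCSC_RefGene_Name": gene_of,
            "DIST_TSS": _sample_tss_distances(rng, cfg.n_probes, cfg.tss_distance_model),
            "IMPRINT": imprint,
        },
        index=pd.Index(probe_ids, name="IlmnID"),
    )
    return manifest


def manifest_gene_map(manifest: pd.DataFrame) -> pd.DataFrame:
    """Exploded (probe, gene) link table; multi-gene probes contribute one
    row per distinct symbol."""
    s = manifest["UCSC_RefGene_Name"]
    rows = []
    for probe, val in s.items():
        if not val:
            continue
        for g in dict.fromkeys(str(val).split(";")):  # de-dup, keep order
            if g:
                rows.append((probe, g))
    return pd.DataFrame(rows, columns=["probe", "gene"])


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------

def _solve_group_shift(m_free: np.ndarray, fixed_centers: np.ndarray, target: float) -> float:
    """Find the logit-space shift so that the median of all probe centers
    (shifted free baseline plus fixed planted/imprinted centers) equals the
    target group median. Monotone in the shift -> bisection."""

    def med(delta: float) -> float:
        centers = np.concatenate([_expit2(m_free + delta), fixed_centers])
        return float(np.median(centers))

    lo, hi = -30.0, 30.0
    if not (med(lo) <= target <= med(hi)):
        raise ValueError("target group median unreachable; inconsistent config")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if med(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_beta(
    cfg: SimulationConfig, manifest: pd.DataFrame, return_planting: bool = False
):
    """β matrix with planted group medians, imprint profiles and DM effects.

    Planted DM probes are disjoint across pathological groups and exclude
    imprinted probes; each carries a Δβ offset of the configured magnitude
    against the baseline of the contrast analysed downstream (PLA and CC
    against VT, MOLE against PLA). Raises if a planted center would leave
    (0,1) or the targets are otherwise unreachable.

    Returns the BetaMatrix, and with ``return_planting=True`` also a record
    of planted probes (probe, group, contrast, direction, category, effect).
    """
    cfg.validate()
    if not manifest.index.is_unique:
        raise ValueError("manifest probe ids must be unique")
    rng = _rng(cfg.seed, "beta")
    n = len(manifest)
    probe_ids = manifest.index

    # bimodal 450K-like baseline in logit space
    low = rng.random(n) < 0.55
    m_base = np.where(
        low,
        rng.normal(_logit2(0.12), 1.0, n),
        rng.normal(_logit2(0.80), 1.0, n),
    )

    imprint = manifest["IMPRINT"].to_numpy()
    is_imprinted = imprint != ""

    # ---- choose planted DM probes (disjoint across groups) ----
    eligible = np.flatnonzero(~is_imprinted)
    eligible = rng.permutation(eligible)
    n_dm = int(round(cfg.frac_dm_probes * n))
    effects = dict(zip(_CATEGORIES, cfg.dm_effect_sizes))

    plan_rows = []  # (probe_idx, group, direction ±1, category, effect)
    taken = np.zeros(n, dtype=bool)
    for g in PATHOLOGICAL_GROUPS:
        if n_dm == 0:
            continue
        hyper = rng.random(n_dm) < cfg.dm_hyper_fraction[g]
        cats = rng.choice(3, size=n_dm, p=np.asarray(cfg.dm_category_weights[g], dtype=float))
        for i in range(n_dm):
            plan_rows.append([g, 1 if hyper[i] else -1, _CATEGORIES[cats[i]], effects[_CATEGORIES[cats[i]]]])
    plan = pd.DataFrame(plan_rows, columns=["group", "direction", "category", "effect"])

    # ---- per-group centers, groups in dependency order ----
    centers: Dict[str, np.ndarray] = {}
    shifts: Dict[str, float] = {}
    baseline: Dict[str, np.ndarray] = {}
    plan["probe_idx"] = -1

    for g in GROUPS:
        fixed_mask = np.zeros(n, dtype=bool)
        fixed_vals = np.zeros(n)
        for cls in IMPRINT_CLASSES:
            m = imprint == cls
            fixed_mask |= m
            fixed_vals[m] = cfg.imprint_beta_profile[(cls, g)]

        # assign planted probes for this group against its reference baseline
        gmask = plan["group"] == g
        if gmask.any():
            ref_group = CONTRASTS[PLANT_CONTRAST[g]][1]
            ref_centers = baseline[ref_group]  # computed earlier (GROUPS order)
            free_arr = eligible[~taken[eligible]]
            # place planted effects on probes where the offset center stays
            # inside (0,1); one draw per (direction, effect) cell
            for (sign, eff), cell in plan.loc[gmask].groupby(["direction", "effect"]):
                sign, eff = int(sign), float(eff)
                c_target = ref_centers[free_arr] + sign * eff
                feasible = free_arr[
                    (c_target > _CENTER_MARGIN) & (c_target < 1.0 - _CENTER_MARGIN)
                ]
                if len(feasible) < len(cell):
                    raise ValueError(
                        f"cannot place {len(cell)} {'hyper' if sign > 0 else 'hypo'} "
                        f"effects of size {eff} for group {g}: planted centers "
                        "would leave (0,1)"
                    )
                chosen = rng.choice(feasible, size=len(cell), replace=False)
                plan.loc[cell.index, "probe_idx"] = chosen
                taken[chosen] = True
                free_arr = free_arr[~taken[free_arr]]
                fixed_mask[chosen] = True
                fixed_vals[chosen] = ref_centers[chosen] + sign * eff

        delta = _solve_group_shift(
            m_base[~fixed_mask], fixed_vals[fixed_mask], cfg.group_median_beta[g]
        )
        shifts[g] = delta
        c = _expit2(m_base + delta)
        c[fixed_mask] = fixed_vals[fixed_mask]
        centers[g] = np.clip(c, _CENTER_MARGIN, 1.0 - _CENTER_MARGIN)
        baseline[g] = _expit2(m_base + delta)  # un-planted baseline for references

    # ---- sample β ----
    cols = {}
    groups = {}
    kappa = cfg.beta_concentration
    for g in GROUPS:
        c = centers[g]
        a, b = c * kappa, (1.0 - c) * kappa
        for s in range(cfg.samples_per_group[g]):
            name = f"{g}_{s + 1:02d}"
            cols[name] = rng.beta(a, b)
            groups[name] = g
    values = pd.DataFrame(cols, index=probe_ids).clip(0.0, 1.0)
    bm = BetaMatrix(values=values, groups=pd.Series(groups))

    if not return_planting:
        return bm
    plan["probe"] = probe_ids[plan["probe_idx"].to_numpy()]
    plan["contrast"] = plan["group"].map(PLANT_CONTRAST)
    planting = plan[["probe", "group", "contrast", "direction", "category", "effect"]].reset_index(
        drop=True
    )
    return bm, planting


def planted_gene_directions(planting: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Gene-level planted methylation direction per contrast.

    A gene inherits the direction of its planted probes when they agree;
    genes with conflicting planted directions are dropped (they would be
    'ambiguous' downstream).
    """
    links = manifest_gene_map(manifest)
    merged = planting.merge(links, on="probe")
    agg = merged.groupby(["contrast", "gene"])["direction"].agg(["min", "max"])
    clean = agg[(agg["min"] == agg["max"])].reset_index()
    clean["direction"] = clean["min"]
    return clean[["contrast", "gene", "direction"]]


# ---------------------------------------------------------------------------
# gene annotation + gene sets
# ---------------------------------------------------------------------------

def generate_gene_annotation(cfg: SimulationConfig, manifest: pd.DataFrame) -> pd.DataFrame:
    """Flags genes as PPE (predominantly placenta-expressed), TBDE
    (trophoblast-differentiation-expressed, with a characteristic direction),
    and imprinted (linked to an imprinted probe)."""
    rng = _rng(cfg.seed, "annotation")
    links = manifest_gene_map(manifest)
    genes = sorted(links["gene"].unique())
    imprinted_probes = set(manifest.index[manifest["IMPRINT"] != ""])
    imprinted_genes = set(links.loc[links["probe"].isin(imprinted_probes), "gene"])
    n = len(genes)
    is_ppe = rng.random(n) < cfg.frac_ppe
    is_tbde = rng.random(n) < cfg.frac_tbde
    tbde_dir = np.where(rng.random(n) < 0.5, 1, -1)
    return pd.DataFrame(
        {
            "is_ppe": is_ppe,
            "is_tbde": is_tbde,
            "tbde_direction": np.where(is_tbde, tbde_dir, 0),
            "is_imprinted": [g in imprinted_genes for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )


def generate_gene_sets(
    cfg: SimulationConfig,
    genes,
    n_sets: int = 50,
    size_range: Tuple[int, int] = (10, 100),
) -> Dict[str, list]:
    """Random gene-set collection (pathway stand-in) over the gene universe."""
    rng = _rng(cfg.seed, "genesets")
    genes = list(genes)
    hi = min(size_range[1], len(genes))
    lo = min(size_range[0], hi)
    return {
        f"SET{i + 1:04d}": sorted(rng.choice(genes, size=rng.integers(lo, hi + 1), replace=False))
        for i in range(n_sets)
    }


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    cfg: SimulationConfig,
    gene_annotation: pd.DataFrame,
    planted_meth: Optional[pd.DataFrame] = None,
) -> Dict[str, DETable]:
    """Two DE tables (RNA-Seq-style mole contrast, microarray-style CC
    contrast) whose stated thresholds select exactly the planted DE set.

    Direction of a planted DE gene: if the gene carries a planted methylation
    direction for the contrast, it is coupled (hyper → down, hypo → up) with
    probability ``coupling_strength``; otherwise the contrast's direction
    bias applies.
    """
    cfg.validate()
    genes = list(gene_annotation.index)
    out: Dict[str, DETable] = {}
    for contrast, (q_max, min_fc) in DE_THRESHOLDS.items():
        # independent substream per contrast (stable tag, not hash())
        tag = sum(ord(ch) for ch in contrast)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed), _STREAMS["expression"], tag])
        )
        n = len(genes)
        n_de = int(round(cfg.frac_de[contrast] * n))
        de_idx = rng.choice(n, size=n_de, replace=False)
        is_de = np.zeros(n, dtype=bool)
        is_de[de_idx] = True

        meth_dir = {}
        if planted_meth is not None:
            sub = planted_meth[planted_meth["contrast"] == contrast]
            meth_dir = dict(zip(sub["gene"], sub["direction"]))

        bias = cfg.de_direction_bias[contrast]
        coupling = cfg.coupling_strength[contrast]
        sign = np.empty(n, dtype=int)
        u = rng.random(n)
        v = rng.random(n)
        for i, g in enumerate(genes):
            md = meth_dir.get(g, 0)
            if is_de[i] and md != 0:
                # coupled: hypermethylated -> downregulated, hypo -> up
                sign[i] = -md if v[i] < coupling else md
            else:
                sign[i] = 1 if u[i] < bias else -1

        log2fc = np.where(
            is_de,
            sign * (np.log2(min_fc) + rng.exponential(0.8, n)),
            np.clip(rng.normal(0.0, 0.3, n), -0.95, 0.95),
        )
        q = np.where(is_de, rng.uniform(0.0, 0.8 * q_max, n), rng.uniform(0.0, 1.0, n))
        df = pd.DataFrame({"gene": genes, "log2fc": log2fc, "qvalue": q})
        out[contrast] = DETable(contrast=contrast, table=df, q_max=q_max, min_abs_fc=min_fc)
    return out


# ---------------------------------------------------------------------------
# immunoscores
# ---------------------------------------------------------------------------

def generate_immunoscores(
    n_control: int,
    n_case: int,
    shift: float,
    seed: int,
    base_mean: float = 5.14,
    donor_sd: float = 1.3,
    noise_sd: float = 0.6,
) -> pd.DataFrame:
    """Tissue-microarray immunoscore table with a hierarchical design:
    2–3 cores per donor, 2–6 annotations per core; annotation score =
    group mean + donor effect + noise, case group shifted by ``shift``."""
    if n_control < 1 or n_case < 1:
        raise ValueError("need at least one donor per group")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS["immuno"]]))
    rows = []
    for group, count, gmean in (
        ("control", n_control, base_mean),
        ("mole", n_case, base_mean + shift),
    ):
        for d in range(1, count + 1):
            donor = f"{group}_{d:02d}"
            donor_eff = rng.normal(0.0, donor_sd)
            for c in range(1, int(rng.integers(2, 4)) + 1):
                for a in range(1, int(rng.integers(2, 7)) + 1):
                    score = max(0.0, gmean + donor_eff + rng.normal(0.0, noise_sd))
                    rows.append((donor, group, f"core{c}", f"ann{a}", score))
    return pd.DataFrame(rows, columns=["donor", "group", "core", "annotation", "score"])
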