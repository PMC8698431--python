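"""Methylation–expression integration.

Matches gene-level methylation calls (UM upmethylated / DM downmethylated)
with differential-expression selections (UR upregulated / DR downregulated)
from two contrasts — mole vs placenta (RNA-Seq-style) and choriocarcinoma
vs villous trophoblast (microarray-style) — and partitions the qualifying
genes into the 12 subsets {M&C, M, C} × {UM/DR, DM/UR, UM/UR, DM/DR}.
UM/DR and DM/UR are the 'regulation-likely' pairs (methylation plausibly
drives the expression change); the other two run counter to expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import DE_THRESHOLDS

PAIRS: Tuple[str, ...] = ("UM/DR", "DM/UR", "UM/UR", "DM/DR")
SCOPES: Tuple[str, ...] = ("M&C", "M", "C")
SUBSET_LABELS: Tuple[str, ...] = tuple(f"{s} {p}" for s in SCOPES for p in PAIRS)
REGULATION_LIKELY: Tuple[str, ...] = ("UM/DR", "DM/UR")

#: subset scope prefix -> integration contrast
SCOPE_CONTRAST = {"M": "MOLEvsPLA", "C": "CCvsVT"}


@dataclass
class DETable:
    """One contrast's differential-expression table with its thresholds."""

    contrast: str
    table: pd.DataFrame  # columns: gene, log2fc, qvalue
    q_max: float = None
    min_abs_fc: float = None

    def __post_init__(self) -> None:
        required = {"gene", "log2fc", "qvalue"}
        if not required <= set(self.table.columns):
            raise ValueError(f"DE table must carry columns {sorted(required)}")
        if self.q_max is None or self.min_abs_fc is None:
            if self.contrast not in DE_THRESHOLDS:
                raise ValueError(
                    f"no default thresholds for contrast {self.contrast!r}; "
                    "pass q_max and min_abs_fc explicitly"
                )
            q, fc = DE_THRESHOLDS[self.contrast]
            self.q_max = q if self.q_max is None else self.q_max
            self.min_abs_fc = fc if self.min_abs_fc is None else self.min_abs_fc


def select_de(de: DETable) -> pd.Series:
    """Significant genes and their direction (+1 up / −1 down).

    Selection: q < q_max and |fold change| ≥ min_abs_fc (i.e. |log2fc| ≥
    log2(min_abs_fc), boundary inclusive). Duplicate gene rows are rejected.
    """
    t = de.table
    if t["gene"].duplicated().any():
        dups = t.loc[t["gene"].duplicated(), "gene"].head().tolist()
        raise ValueError(f"duplicate gene rows in DE table: {dups}")
    min_l2 = np.log2(de.min_abs_fc)
    sel = t[(t["qvalue"] < de.q_max) & (t["log2fc"].abs() >= min_l2)]
    return pd.Series(
        np.where(sel["log2fc"] > 0, 1, -1), index=pd.Index(sel["gene"], name="gene"), dtype=int
    )


@dataclass
class SubsetPartition:
    """The 12-way {M&C, M, C} × {UM/DR, DM/UR, UM/UR, DM/DR} gene partition."""

    subsets: Dict[str, Set[str]]
    #: genes qualifying in both contrasts with conflicting direction pairs;
    #: these sit in both single-contrast subsets, never in M&C (documented
    #: deviation from strict disjointness)
    conflicting: Set[str] = field(default_factory=set)

    def membership(self) -> pd.DataFrame:
        rows = [
            (gene, label, label.split(" ", 1)[1] in REGULATION_LIKELY)
            for label in SUBSET_LABELS
            for gene in sorted(self.subsets[label])
        ]
        return pd.DataFrame(rows, columns=["gene", "subset", "regulation_likely"])

    def all_genes(self) -> Set[str]:
        out: Set[str] = set()
        for s in self.subsets.values():
            out |= s
        return out


def _pair_label(meth_call: str, de_dir: int) -> str:
    um = meth_call == "hyper"
    ur = de_dir > 0
    if um and not ur:
        return "UM/DR"
    if not um and ur:
        return "DM/UR"
    if um and ur:
        return "UM/UR"
    return "DM/DR"


def build_partition(
    calls_m: pd.DataFrame,
    calls_c: pd.DataFrame,
    de_m: pd.Series,
    de_c: pd.Series,
) -> SubsetPartition:
    """Partition genes that are both DM and DE in at least one contrast.

    A gene qualifies in a contrast when its methylation call is hyper or
    hypo (ambiguous genes were excluded at the call stage and are dropped
    here defensively) AND it is DE-selected in that contrast. Genes
    qualifying in both contrasts with the same (methylation, expression)
    direction pair land in the M&C subset of that pair; with different
    pairs, in both single-contrast subsets.
    """
    def qualifying(calls: pd.DataFrame, de: pd.Series) -> Dict[str, str]:
        ok = calls[calls["call"].isin(["hyper", "hypo"])]
        out = {}
        for gene, call in zip(ok["gene"], ok["call"]):
            if gene in de.index:
                out[gene] = _pair_label(call, int(de.loc[gene]))
        return out

    pair_m = qualifying(calls_m, de_m)
    pair_c = qualifying(calls_c, de_c)
    subsets: Dict[str, Set[str]] = {label: set() for label in SUBSET_LABELS}
    conflicting: Set[str] = set()
    for gene in set(pair_m) | set(pair_c):
        in_m, in_c = gene in pair_m, gene in pair_c
        if in_m and in_c:
            if pair_m[gene] == pair_c[gene]:
                subsets[f"M&C {pair_m[gene]}"].add(gene)
            else:
                subsets[f"M {pair_m[gene]}"].add(gene)
                subsets[f"C {pair_c[gene]}"].add(gene)
                conflicting.add(gene)
        elif in_m:
            subsets[f"M {pair_m[gene]}"].add(gene)
        else:
            subsets[f"C {pair_c[gene]}"].add(gene)
    return SubsetPartition(subsets=subsets, conflicting=conflicting)


def partition_counts(
    partition: SubsetPartition, annotation: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """12-row counts table: all genes plus imprinted / PPE / TBDE columns."""
    rows = {}
    for label in SUBSET_LABELS:
        genes = partition.subsets[label]
        row = {"n_genes": len(genes)}
        if annotation is not None:
            present = [g for g in genes if g in annotation.index]
            sub = annotation.loc[present]
            row["imprinted"] = int(sub["is_imprinted"].sum())
            row["ppe"] = int(sub["is_ppe"].sum())
            row["tbde"] = int(sub["is_tbde"].sum())
        else:
            row.update({"imprinted": 0, "ppe": 0, "tbde": 0})
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index").loc[list(SUBSET_LABELS)]


def partition_summary(counts: pd.DataFrame | SubsetPartition) -> Dict[str, object]:
    """Derived aggregates of the 12-subset counts table.

    Accepts either a SubsetPartition or a counts table indexed by the 12
    subset labels (column ``n_genes`` plus optional annotation-class
    columns). Reports, per contrast, the number of involved genes, the
    hyper/hypomethylated split, and the up/down split within each, with
    fractions kept at full precision (display layers round).
    """
    if isinstance(counts, SubsetPartition):
        counts = partition_counts(counts)
    missing = [l for l in SUBSET_LABELS if l not in counts.index]
    if missing:
        raise ValueError(f"counts table missing subset rows: {missing}")
    n = counts["n_genes"]

    def rows_for(scope: str) -> list:
        return [f"{s} {p}" for s in ("M&C", scope) for p in PAIRS]

    summary: Dict[str, object] = {
        "total": int(n.sum()),
        "column_totals": {c: int(counts[c].sum()) for c in counts.columns},
    }
    for scope, key in (("M", "mole"), ("C", "cc")):
        labels = rows_for(scope)
        involved = int(n[labels].sum())
        hyper = int(sum(n[l] for l in labels if "UM/" in l))
        hypo = int(sum(n[l] for l in labels if "DM/" in l))
        hyper_down = int(sum(n[l] for l in labels if l.endswith("UM/DR")))
        hyper_up = int(sum(n[l] for l in labels if l.endswith("UM/UR")))
        hypo_up = int(sum(n[l] for l in labels if l.endswith("DM/UR")))
        hypo_down = int(sum(n[l] for l in labels if l.endswith("DM/DR")))
        summary[key] = {
            "involved": involved,
            "hyper": hyper,
            "hypo": hypo,
            "frac_hyper": hyper / involved if involved else np.nan,
            "frac_hypo": hypo / involved if involved else np.nan,
            "hyper_down": hyper_down,
            "hyper_up": hyper_up,
            "frac_hyper_down": hyper_down / hyper if hyper else np.nan,
            "frac_hyper_up": hyper_up / hyper if hyper else np.nan,
            "hypo_up": hypo_up,
            "hypo_down": hypo_down,
            "frac_hypo_up": hypo_up / hypo if hypo else np.nan,
            "frac_hypo_down": hypo_down / hypo if hypo else np.nan,
        }
    return summary


@dataclass
class ConcordanceResult:
    """Direction agreement of DE genes with the differentiation signature."""

    contrast: str
    n_tbde_de: int
    n_same_direction: int
    n_opposite: int
    fraction_same: float  # NaN when no TBDE gene is selected


def concordance_with_differentiation(
    de_selection: pd.Series, tbde_direction: Mapping[str, int], contrast: str = ""
) -> ConcordanceResult:
    """Compare DE directions of trophoblast-differentiation (TBDE) genes with
    their characteristic differentiation direction.

    ``tbde_direction`` maps gene → ±1; genes without a defined direction
    (0 or missing) are excluded from the denominator.
    """
    same = opposite = 0
    for gene, de_dir in de_selection.items():
        d = tbde_direction.get(gene, 0)
        if d == 0:
            continue
        if int(np.sign(d)) == int(np.sign(de_dir)):
            same += 1
        else:
            opposite += 1
    n = same + opposite
    return ConcordanceResult(
        contrast=contrast,
        n_tbde_de=n,
        n_same_direction=same,
        n_opposite=opposite,
        fraction_same=same / n if n else float("nan"),
    )


@dataclass
class EnrichmentOR:
    """2×2 enrichment of a gene class among DE genes."""

    table: Tuple[int, int, int, int]  # (a, b, c, d) = (class∩DE, class∖DE, DE∖class, rest)
    odds_ratio: float
    fisher_p: float
    haldane_corrected: bool


def enrichment_or(
    de_genes: Iterable[str], class_genes: Iterable[str], universe: Iterable[str]
) -> EnrichmentOR:
    """Odds ratio (a·d)/(b·c) and two-sided Fisher exact p for the 2×2 table
    of class membership × DE status over the universe. Haldane's 0.5
    continuity correction is applied to the OR only when a cell is zero
    (flagged); the p-value always uses the uncorrected table."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    de = set(de_genes) & uni
    cls = set(class_genes) & uni
    a = len(cls & de)
    b = len(cls - de)
    c = len(de - cls)
    d = len(uni) - a - b - c
    haldane = 0 in (a, b, c, d)
    if haldane:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentOR(
        table=(a, b, c, d), odds_ratio=float(odds), fisher_p=float(p), haldane_corrected=haldane
    )
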