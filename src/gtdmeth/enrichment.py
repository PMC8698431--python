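"""Generic over-representation analysis against a gene-set collection.

Replaces a web-service pathway tool with a reproducible hypergeometric
over-representation test; an EASE mode (overlap reduced by one, the
conservative modified Fisher variant popularised by DAVID) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List

import pandas as pd
from scipy import stats

from .diffmeth import bh_qvalues


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit gene universe.

    Members outside the universe are filtered out; sets left empty are
    dropped with a warning.
    """

    sets: Dict[str, List[str]]
    universe: List[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        cleaned = {}
        for name, members in self.sets.items():
            kept = sorted(set(members) & uni)
            if not kept:
                warnings.warn(f"gene set {name!r} is empty after universe filtering; dropped")
                continue
            cleaned[name] = kept
        self.sets = cleaned

    @classmethod
    def from_gmt(cls, path, universe: Iterable[str]) -> "GeneSetCollection":
        from gseapy.parser import read_gmt

        return cls(sets={k: list(v) for k, v in read_gmt(str(path)).items()},
                   universe=list(universe))


def overrepresentation(
    query: Iterable[str],
    gsc: GeneSetCollection,
    min_overlap: int = 2,
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query gene set.

    For each set with overlap ≥ ``min_overlap``: upper-tail hypergeometric
    p (P[X ≥ overlap] drawing |query| genes from the universe), BH q across
    the tested sets, and fold enrichment
    (overlap/|query|) / (|set|/|universe|). ``ease=True`` subtracts one from
    the overlap before computing p. Query genes outside the universe are
    reported via a warning and trimmed.
    """
    uni = set(gsc.universe)
    q = set(query)
    outside = q - uni
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe were trimmed")
        q &= uni
    if not q:
        raise ValueError("empty query after universe trimming")
    N, n = len(uni), len(q)
    rows = []
    for name, members in gsc.sets.items():
        K = len(members)
        a = len(q & set(members))
        if a < min_overlap:
            continue
        x = a - 1 if ease else a
        p = float(stats.hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
        fold = (a / n) / (K / N)
        rows.append((name, a, K, fold, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "fold_enrichment", "p"])
    out = out.sort_values("p", kind="stable").reset_index(drop=True)
    out["q"] = bh_qvalues(out["p"]) if len(out) else out["p"]
    return out
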