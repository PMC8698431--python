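"""Readers and writers for the plain-text interchange formats.

Manifest CSV (IlmnID, CHR, MAPINFO, UCSC_RefGene_Name, DIST_TSS, IMPRINT),
β matrix TSV (probes × samples) with a sample-map TSV, DE tables TSV
(gene, log2fc, qvalue), gene-annotation TSV, gene sets GMT, and
immunoscore TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Optional

import pandas as pd

from .core import BetaMatrix
from .integration import DETable

FLOAT_FMT = "%.6g"


# -- manifest ---------------------------------------------------------------

def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index_label="IlmnID")


def read_manifest(path) -> pd.DataFrame:
    m = pd.read_csv(path, index_col="IlmnID", keep_default_na=False, dtype={"CHR": str})
    m["DIST_TSS"] = m["DIST_TSS"].astype(int)
    return m


# -- beta matrix ------------------------------------------------------------

def write_beta(bm: BetaMatrix, beta_path, samplemap_path) -> None:
    bm.values.to_csv(beta_path, sep="\t", index_label="probe", float_format=FLOAT_FMT)
    bm.groups.rename("group").to_csv(samplemap_path, sep="\t", index_label="sample")


def read_beta(beta_path, samplemap_path) -> BetaMatrix:
    values = pd.read_csv(beta_path, sep="\t", index_col="probe")
    groups = pd.read_csv(samplemap_path, sep="\t", index_col="sample")["group"]
    return BetaMatrix(values=values, groups=groups)


# -- DE tables --------------------------------------------------------------

def write_de_table(de: DETable, path) -> None:
    de.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_de_table(
    path, contrast: str, q_max: Optional[float] = None, min_abs_fc: Optional[float] = None
) -> DETable:
    t = pd.read_csv(path, sep="\t")
    return DETable(contrast=contrast, table=t, q_max=q_max, min_abs_fc=min_abs_fc)


# -- gene annotation --------------------------------------------------------

def write_gene_annotation(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index_label="gene")


def read_gene_annotation(path) -> pd.DataFrame:
    a = pd.read_csv(path, sep="\t", index_col="gene")
    for c in ("is_ppe", "is_tbde", "is_imprinted"):
        a[c] = a[c].astype(bool)
    a["tbde_direction"] = a["tbde_direction"].astype(int)
    return a


# -- gene sets (GMT) --------------------------------------------------------

def write_gmt(sets: Dict[str, Iterable[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gmt(path) -> Dict[str, List[str]]:
    from gseapy.parser import read_gmt as _read

    return {k: list(v) for k, v in _read(str(path)).items()}


# -- immunoscores -----------------------------------------------------------

def write_immunoscores(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_immunoscores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- per-probe / per-gene results -------------------------------------------

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
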