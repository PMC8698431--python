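"""End-to-end pipeline: simulate → DM testing → gene calls → DE matching →
12-subset partition → enrichment → report.

The report mirrors the layout of the integrative study's summary table
(12 subset rows × annotation-class columns) plus the derived per-contrast
percentage lines, and embeds a provenance block with every threshold and
the seed, so a rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import io
from .config import SimulationConfig
from .core import cluster_samples, group_medians, imprint_distributions
from .diffmeth import (
    DELTA_BETA_BINS,
    Q_MODERATED,
    Q_TTEST,
    call_genes,
    dm_moderated,
    dm_ttest_contrast,
    tss_profile,
)
from .enrichment import GeneSetCollection, overrepresentation
from .integration import (
    REGULATION_LIKELY,
    build_partition,
    concordance_with_differentiation,
    enrichment_or,
    partition_counts,
    partition_summary,
    select_de,
)
from .simulate import (
    generate_beta,
    generate_expression,
    generate_gene_annotation,
    generate_gene_sets,
    generate_manifest,
    planted_gene_directions,
)

INTEGRATION_CONTRASTS = ("MOLEvsPLA", "CCvsVT")


@dataclass
class PipelineConfig:
    """Thresholds, routing and output options for a full run."""

    out_dir: str = "gtd_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    q_dm: float = Q_TTEST
    q_moderated: float = Q_MODERATED
    min_abs_delta_beta: float = DELTA_BETA_BINS[0]
    tss_bin_width: int = 100
    routing: str = "auto"  # 'auto' (F-routed t-test) or 'moderated'

    def __post_init__(self) -> None:
        if not (0 < self.q_dm < 1 and 0 < self.q_moderated < 1):
            raise ValueError("q thresholds must lie in (0,1)")
        if not (0 <= self.min_abs_delta_beta < 1):
            raise ValueError("min_abs_delta_beta must lie in [0,1)")
        if self.routing not in ("auto", "moderated"):
            raise ValueError("routing must be 'auto' or 'moderated'")
        if self.tss_bin_width not in (100, 200):
            raise ValueError("tss_bin_width must be 100 or 200")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", {})
        if "imprint_beta_profile" in sim_raw:
            sim_raw["imprint_beta_profile"] = {
                tuple(k.split(":")): v for k, v in sim_raw["imprint_beta_profile"].items()
            }
        if "dm_effect_sizes" in sim_raw:
            sim_raw["dm_effect_sizes"] = tuple(sim_raw["dm_effect_sizes"])
        sim = SimulationConfig(**sim_raw)
        return cls(simulation=sim, **raw)


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Run every stage on a simulated dataset and write the report bundle.

    Returns the report dict; all stage outputs are written under
    ``cfg.out_dir`` as plain-text tables so any stage can be re-run from
    its files.
    """
    out = io.ensure_dir(cfg.out_dir)
    sim = cfg.simulation
    if sim.seed != cfg.seed:
        sim = SimulationConfig(**{**sim.to_dict(), "seed": cfg.seed,
                                  "imprint_beta_profile": sim.imprint_beta_profile})

    # ---- simulate ----
    manifest = generate_manifest(sim)
    bm, planting = generate_beta(sim, manifest, return_planting=True)
    gene_annot = generate_gene_annotation(sim, manifest)
    planted = planted_gene_directions(planting, manifest)
    de_tables = generate_expression(sim, gene_annot, planted)
    gene_sets = generate_gene_sets(sim, gene_annot.index)

    io.write_manifest(manifest, out / "manifest.csv")
    io.write_beta(bm, out / "beta.tsv", out / "samples.tsv")
    io.write_gene_annotation(gene_annot, out / "gene_annotation.tsv")
    io.write_gmt(gene_sets, out / "gene_sets.gmt")
    for contrast, det in de_tables.items():
        io.write_de_table(det, out / f"de_{contrast}.tsv")

    # ---- methylation descriptives ----
    medians = group_medians(bm)
    clust = cluster_samples(bm)
    imprints = imprint_distributions(bm, manifest)
    io.write_table(
        pd.DataFrame(clust.linkage, columns=["left", "right", "height", "size"]),
        out / "linkage.tsv",
    )

    # ---- differential methylation + gene calls ----
    calls = {}
    dm_frames = {}
    for contrast in INTEGRATION_CONTRASTS:
        if cfg.routing == "moderated":
            dm = dm_moderated(bm, contrast, q_threshold=cfg.q_moderated)
            q_thr = cfg.q_moderated
        else:
            dm = dm_ttest_contrast(bm, contrast, q_threshold=cfg.q_dm)
            q_thr = cfg.q_dm
        dm_frames[contrast] = dm
        io.write_table(dm, out / f"dm_{contrast}.tsv")
        gc = call_genes(dm, manifest, cfg.min_abs_delta_beta, q_thr)
        calls[contrast] = gc
        io.write_table(gc, out / f"genecalls_{contrast}.tsv")
        for direction in ("hyper", "hypo"):
            prof = tss_profile(dm, manifest, direction, bin_width=cfg.tss_bin_width)
            io.write_table(
                pd.DataFrame(
                    {
                        "bin_start": prof.bin_edges[:-1],
                        "bin_end": prof.bin_edges[1:],
                        "count": prof.counts,
                        "frequency": prof.frequencies
                        if prof.frequencies is not None
                        else float("nan"),
                    }
                ),
                out / f"tss_{contrast}_{direction}.tsv",
            )

    # ---- integration ----
    de_sel = {c: select_de(de_tables[c]) for c in INTEGRATION_CONTRASTS}
    partition = build_partition(
        calls["MOLEvsPLA"], calls["CCvsVT"], de_sel["MOLEvsPLA"], de_sel["CCvsVT"]
    )
    counts = partition_counts(partition, gene_annot)
    summary = partition_summary(counts)
    io.write_table(partition.membership(), out / "partition_membership.tsv")
    io.write_table(counts, out / "partition_counts.tsv", index=True)

    tbde_dir = dict(
        gene_annot.loc[gene_annot["is_tbde"], "tbde_direction"].items()
    )
    concordance = {
        c: concordance_with_differentiation(de_sel[c], tbde_dir, contrast=c).__dict__
        for c in INTEGRATION_CONTRASTS
    }
    universe = list(gene_annot.index)
    enrich_or = {
        c: {
            cls: enrichment_or(de_sel[c].index, gene_annot.index[gene_annot[flag]], universe).__dict__
            for cls, flag in (("ppe", "is_ppe"), ("tbde", "is_tbde"), ("imprinted", "is_imprinted"))
        }
        for c in INTEGRATION_CONTRASTS
    }

    # ---- pathway enrichment of the regulation-likely subsets ----
    gsc = GeneSetCollection(sets=gene_sets, universe=universe)
    pathway = {}
    for scope, contrast in (("M", "MOLEvsPLA"), ("C", "CCvsVT")):
        genes = set()
        for pair in REGULATION_LIKELY:
            genes |= partition.subsets[f"{scope} {pair}"]
            genes |= partition.subsets[f"M&C {pair}"]
        if genes:
            res = overrepresentation(genes, gsc)
            io.write_table(res, out / f"enrichment_{contrast}.tsv")
            pathway[contrast] = int((res["q"] < 0.1).sum())
        else:
            pathway[contrast] = 0

    report = {
        "provenance": {
            "seed": cfg.seed,
            "q_dm": cfg.q_dm,
            "q_moderated": cfg.q_moderated,
            "min_abs_delta_beta": cfg.min_abs_delta_beta,
            "routing": cfg.routing,
            "tss_bin_width": cfg.tss_bin_width,
            "simulation": sim.to_dict(),
            "de_thresholds": {
                c: {"q_max": de_tables[c].q_max, "min_abs_fc": de_tables[c].min_abs_fc}
                for c in INTEGRATION_CONTRASTS
            },
        },
        "group_median_beta": {k: round(v, 6) for k, v in medians.items()},
        "clade_purity": {k: round(v, 6) for k, v in clust.purity.items()},
        "imprints": {
            d.imprint_class: (None if d.empty else {
                g: round(float(d.summary.loc[g, "median"]), 6) for g in d.summary.index
            })
            for d in imprints
        },
        "n_dm_probes": {
            c: int(dm_frames[c]["significant"].sum()) for c in INTEGRATION_CONTRASTS
        },
        "n_de_genes": {c: int(len(de_sel[c])) for c in INTEGRATION_CONTRASTS},
        "partition_counts": counts["n_genes"].to_dict(),
        "summary": summary,
        "concordance": concordance,
        "enrichment_or": enrich_or,
        "n_enriched_sets_q10": pathway,
        "n_conflicting_genes": len(partition.conflicting),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return report
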