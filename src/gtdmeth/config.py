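"""Simulation and pipeline configuration objects.

The simulation emulates the statistical structure of an Illumina 450K
methylation study of gestational trophoblastic disease: four sample groups
(villous trophoblast VT, first-trimester placenta PLA, complete mole MOLE,
choriocarcinoma CC) with escalating global methylation, parent-of-origin
imprint marks with group-specific asymmetries, planted differential
methylation in three magnitude tiers, and differential-expression tables
whose direction biases and methylation coupling mirror the disease biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Tuple

GROUPS: Tuple[str, ...] = ("VT", "PLA", "MOLE", "CC")
PATHOLOGICAL_GROUPS: Tuple[str, ...] = ("PLA", "MOLE", "CC")

#: DM/DE contrast name -> (target group, reference group)
CONTRASTS: Mapping[str, Tuple[str, str]] = {
    "PLAvsVT": ("PLA", "VT"),
    "MOLEvsVT": ("MOLE", "VT"),
    "MOLEvsPLA": ("MOLE", "PLA"),
    "CCvsVT": ("CC", "VT"),
}

#: Contrast analysed against each pathological group when planting effects.
PLANT_CONTRAST: Mapping[str, str] = {
    "PLA": "PLAvsVT",
    "MOLE": "MOLEvsPLA",
    "CC": "CCvsVT",
}

#: Expression contrasts consumed by the integration stage, with their
#: significance thresholds (q_max, min absolute fold change).
DE_THRESHOLDS: Mapping[str, Tuple[float, float]] = {
    "MOLEvsPLA": (0.05, 2.0),  # RNA-Seq-style contrast
    "CCvsVT": (0.10, 2.0),  # microarray-style contrast
}

IMPRINT_CLASSES: Tuple[str, ...] = ("maternal", "paternal")


def _default_samples() -> dict:
    return {"VT": 19, "PLA": 12, "MOLE": 4, "CC": 4}


def _default_medians() -> dict:
    return {"VT": 0.25, "PLA": 0.37, "MOLE": 0.45, "CC": 0.59}


def _default_imprint_profile() -> dict:
    # Maternal marks: highest in moles, elevated in choriocarcinoma.
    # Paternal marks: erased in moles, gained in choriocarcinoma.
    return {
        ("maternal", "VT"): 0.45,
        ("maternal", "PLA"): 0.50,
        ("maternal", "MOLE"): 0.80,
        ("maternal", "CC"): 0.65,
        ("paternal", "VT"): 0.45,
        ("paternal", "PLA"): 0.50,
        ("paternal", "MOLE"): 0.25,
        ("paternal", "CC"): 0.75,
    }


def _default_hyper_fraction() -> dict:
    return {"PLA": 0.60, "MOLE": 0.67, "CC": 0.96}


def _default_category_weights() -> dict:
    # (mild, moderate, strong); strong effects concentrate in choriocarcinoma.
    return {
        "PLA": (0.75, 0.23, 0.02),
        "MOLE": (0.70, 0.27, 0.03),
        "CC": (0.50, 0.35, 0.15),
    }


def _default_tss_model() -> dict:
    return {
        "p_proximal": 0.55,
        "proximal_max": 200.0,
        "tail_scale": 1200.0,
        "max_distance": 5000.0,
    }


def _default_de_bias() -> dict:
    return {"MOLEvsPLA": 0.72, "CCvsVT": 0.31}


def _default_coupling() -> dict:
    return {"MOLEvsPLA": 0.32, "CCvsVT": 0.71}


def _default_frac_de() -> dict:
    return {"MOLEvsPLA": 0.27, "CCvsVT": 0.14}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic 450K-style dataset.

    Defaults plant the study conditions: group median beta-values
    0.25 / 0.37 / 0.45 / 0.59 for VT / PLA / MOLE / CC, maternal imprint
    marks highest in moles, paternal marks lowest in moles and highest in
    choriocarcinoma, and DE direction biases of 72% up (mole) and
    31% up / 69% down (choriocarcinoma).
    """

    n_probes: int = 20_000
    n_genes: int = 2_000
    samples_per_group: Mapping[str, int] = field(default_factory=_default_samples)
    group_median_beta: Mapping[str, float] = field(default_factory=_default_medians)
    #: pseudo-sample-size of the per-probe Beta noise; within-group sd of a
    #: mid-range probe is ~sqrt(0.25 / concentration) (~0.04 at 150)
    beta_concentration: float = 150.0
    frac_dm_probes: float = 0.08
    dm_effect_sizes: Tuple[float, float, float] = (0.18, 0.35, 0.55)
    dm_hyper_fraction: Mapping[str, float] = field(default_factory=_default_hyper_fraction)
    dm_category_weights: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=_default_category_weights
    )
    frac_imprinted_maternal: float = 0.007
    frac_imprinted_paternal: float = 0.032
    imprint_beta_profile: Mapping[Tuple[str, str], float] = field(
        default_factory=_default_imprint_profile
    )
    tss_distance_model: Mapping[str, float] = field(default_factory=_default_tss_model)
    frac_ppe: float = 0.012
    frac_tbde: float = 0.14
    frac_de: Mapping[str, float] = field(default_factory=_default_frac_de)
    de_direction_bias: Mapping[str, float] = field(default_factory=_default_de_bias)
    #: probability that a planted hypermethylated (hypomethylated) DE gene is
    #: planted downregulated (upregulated), per contrast
    coupling_strength: Mapping[str, float] = field(default_factory=_default_coupling)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_probes < 1 or self.n_genes < 1:
            raise ValueError("n_probes and n_genes must be positive")
        for g in GROUPS:
            if g not in self.samples_per_group:
                raise ValueError(f"samples_per_group missing group {g!r}")
            if self.samples_per_group[g] < 2:
                raise ValueError(f"group {g!r} needs >=2 samples for variance estimation")
            b = self.group_median_beta.get(g)
            if b is None or not (0.0 < b < 1.0):
                raise ValueError(f"group_median_beta[{g!r}] must lie strictly in (0,1)")
        fractions = {
            "frac_dm_probes": self.frac_dm_probes,
            "frac_imprinted_maternal": self.frac_imprinted_maternal,
            "frac_imprinted_paternal": self.frac_imprinted_paternal,
            "frac_ppe": self.frac_ppe,
            "frac_tbde": self.frac_tbde,
            **{f"frac_de[{k}]": v for k, v in self.frac_de.items()},
            **{f"de_direction_bias[{k}]": v for k, v in self.de_direction_bias.items()},
            **{f"coupling_strength[{k}]": v for k, v in self.coupling_strength.items()},
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0,1], got {value}")
        if self.frac_imprinted_maternal + self.frac_imprinted_paternal > 1.0:
            raise ValueError("imprint fractions must sum to <=1 (classes are disjoint)")
        if self.beta_concentration <= 0:
            raise ValueError("beta_concentration must be positive")
        if not all(e > 0 for e in self.dm_effect_sizes):
            raise ValueError("dm_effect_sizes must be positive")
        for cls in IMPRINT_CLASSES:
            for g in GROUPS:
                c = self.imprint_beta_profile.get((cls, g))
                if c is None or not (0.0 < c < 1.0):
                    raise ValueError(f"imprint_beta_profile missing or invalid for ({cls}, {g})")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["imprint_beta_profile"] = {
            f"{cls}:{grp}": v for (cls, grp), v in self.imprint_beta_profile.items()
        }
        return d
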