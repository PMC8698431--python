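"""Differential methylation: routed t-tests, empirical-Bayes moderation,
Δβ categories, gene calls and TSS profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from gtdmeth.core import BetaMatrix
from gtdmeth.diffmeth import (
    bh_qvalues,
    call_genes,
    categorize_delta_beta,
    dm_moderated,
    dm_test_probe,
    dm_ttest_contrast,
    estimate_prior_variance,
    moderated_variance,
    tss_profile,
)

from conftest import brute_force_bh


class TestRoutedTTest:
    def test_identical_samples(self):
        t, p, route = dm_test_probe([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_pooled_t_matches_closed_form(self):
        """Equal variances route to Student; t agrees with the textbook
        pooled-variance formula for n1 = n2 = 3."""
        x, y = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        t, p, route = dm_test_probe(x, y)
        # sp2 = 1, se = sqrt(2/3), t = -10 / se
        expected = -10.0 / np.sqrt(2.0 / 3.0)
        assert route == "student"
        assert t == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(2 * stats.t.sf(abs(expected), 4), rel=1e-12)

    def test_unequal_variances_route_to_welch(self):
        """With a 100x variance ratio at n = 10 the F-test is essentially
        always significant, so nearly every repetition routes to Welch."""
        rng = np.random.default_rng(0)
        routes = []
        for _ in range(200):
            x = rng.normal(0, 1, 10)
            y = rng.normal(0, 10, 10)
            routes.append(dm_test_probe(x, y)[2])
        assert np.mean([r == "welch" for r in routes]) > 0.95

    def test_zero_variance_degenerate_cases(self):
        t, p, route = dm_test_probe([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t, p, route = dm_test_probe([2.0, 2.0], [3.0, 3.0])
        assert p == 0.0 and route == "degenerate"

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            dm_test_probe([1.0], [2.0, 3.0])

    def test_vectorized_contrast_matches_scalar(self):
        rng = np.random.default_rng(2)
        v = pd.DataFrame(
            rng.uniform(0.1, 0.9, (25, 8)),
            index=[f"cg{i}" for i in range(25)],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = pd.Series({f"s{i}": ("CC" if i < 4 else "VT") for i in range(8)})
        bm = BetaMatrix(values=v, groups=groups)
        res = dm_ttest_contrast(bm, "CCvsVT")
        from gtdmeth.core import beta_to_m

        M = beta_to_m(v.to_numpy())
        for i in range(25):
            t, p, route = dm_test_probe(M[i, :4], M[i, 4:])
            assert res.loc[i, "t"] == pytest.approx(t, rel=1e-9)
            assert res.loc[i, "p"] == pytest.approx(p, rel=1e-9)
            assert res.loc[i, "route"] == route

    def test_contrast_antisymmetry(self):
        """Swapping contrast groups negates Δβ and ΔM and keeps p."""
        rng = np.random.default_rng(4)
        v = pd.DataFrame(
            rng.uniform(0.05, 0.95, (40, 9)),
            index=[f"cg{i}" for i in range(40)],
            columns=[f"s{i}" for i in range(9)],
        )
        groups = pd.Series({f"s{i}": ("MOLE" if i < 4 else "PLA") for i in range(9)})
        bm = BetaMatrix(values=v, groups=groups)
        fwd = dm_ttest_contrast(bm, "MOLEvsPLA")
        swapped = BetaMatrix(
            values=v, groups=groups.map({"MOLE": "PLA", "PLA": "MOLE"})
        )
        rev = dm_ttest_contrast(swapped, "MOLEvsPLA")
        np.testing.assert_allclose(fwd["delta_beta"], -rev["delta_beta"], atol=1e-12)
        np.testing.assert_allclose(fwd["delta_m"], -rev["delta_m"], atol=1e-9)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-9)


class TestBH:
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=1000))
    def test_matches_brute_force(self, ps):
        p = np.asarray(ps)
        np.testing.assert_allclose(bh_qvalues(p), brute_force_bh(p), atol=1e-12)

    def test_qvalues_in_unit_interval(self):
        rng = np.random.default_rng(0)
        q = bh_qvalues(rng.random(500))
        assert (q >= 0).all() and (q <= 1).all()


class TestModerated:
    def _bm(self, seed=0, n=200, shift=0.0):
        rng = np.random.default_rng(seed)
        cols, groups = {}, {}
        for g, size in (("VT", 5), ("PLA", 5), ("MOLE", 5), ("CC", 5)):
            for s in range(size):
                name = f"{g}_{s}"
                mu = 0.5 + (shift if g == "CC" else 0.0)
                cols[name] = np.clip(rng.normal(mu, 0.05, n), 0.01, 0.99)
                groups[name] = g
        v = pd.DataFrame(cols, index=[f"cg{i}" for i in range(n)])
        return BetaMatrix(values=v, groups=pd.Series(groups))

    def test_no_shrinkage_limit_equals_ordinary_t(self):
        bm = self._bm()
        mod = dm_moderated(bm, "CCvsVT", d0_override=0)
        # ordinary t from the same one-way fit
        from gtdmeth.core import m_matrix

        M = m_matrix(bm)
        cc = M[[c for c in M if c.startswith("CC")]].to_numpy()
        vt = M[[c for c in M if c.startswith("VT")]].to_numpy()
        rss = np.zeros(len(M))
        for g in ("VT", "PLA", "MOLE", "CC"):
            sub = M[[c for c in M if c.startswith(g)]].to_numpy()
            rss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        s2 = rss / (20 - 4)
        t_ref = (cc.mean(axis=1) - vt.mean(axis=1)) / np.sqrt(s2 * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(mod["t"], t_ref, rtol=1e-9)

    def test_constant_probe_gives_zero_t(self):
        bm = self._bm()
        v = bm.values.copy()
        v.iloc[0] = 0.4
        bm2 = BetaMatrix(values=v, groups=bm.groups)
        mod = dm_moderated(bm2, "CCvsVT")
        assert mod.loc[0, "t"] == 0.0

    def test_shrinkage_concentrates_shared_variance(self):
        """When every probe shares one true variance, the posterior variances
        concentrate around it far more tightly than the raw ones."""
        bm = self._bm(seed=1, n=2000)
        from gtdmeth.core import m_matrix

        M = m_matrix(bm)
        rss = np.zeros(len(M))
        for g in ("VT", "PLA", "MOLE", "CC"):
            sub = M[[c for c in M if c.startswith(g)]].to_numpy()
            rss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        s2 = rss / 16
        d0, s0_2 = estimate_prior_variance(s2, 16)
        s2_tilde = moderated_variance(s2, 16, d0, s0_2)
        assert np.var(s2_tilde) < 0.5 * np.var(s2)
        assert abs(np.median(s2_tilde) - np.median(s2)) < 0.3 * np.median(s2)

    def test_minimum_probe_count_enforced(self):
        bm = self._bm(n=20)
        with pytest.raises(ValueError):
            dm_moderated(bm, "CCvsVT")

    def test_detects_planted_shift(self):
        bm = self._bm(seed=3, shift=0.15)
        mod = dm_moderated(bm, "CCvsVT")
        assert (mod["q"] < 0.05).mean() > 0.9


class TestDeltaBetaCategories:
    @pytest.mark.parametrize(
        "db,cat,direction",
        [
            (0.2, "mild", "hyper"),
            (-0.6, "strong", "hypo"),
            (0.125, "none", "none"),
            (-0.125, "none", "none"),
            (0.25, "mild", "hyper"),
            (0.2501, "moderate", "hyper"),
            (-0.5, "moderate", "hypo"),
            (0.51, "strong", "hyper"),
            (0.0, "none", "none"),
        ],
    )
    def test_bin_assignment(self, db, cat, direction):
        assert categorize_delta_beta(db) == (cat, direction)

    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_bins_partition_the_interval(self, db):
        cat, direction = categorize_delta_beta(db)
        assert cat in {"none", "mild", "moderate", "strong"}
        assert (cat == "none") == (direction == "none")
        if db > 0.125:
            assert direction == "hyper"
        if db < -0.125:
            assert direction == "hypo"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_delta_beta(1.5)


def _dm_frame(rows):
    """rows: (probe, delta_beta, q)"""
    df = pd.DataFrame(rows, columns=["probe", "delta_beta", "q"])
    df["contrast"] = "CCvsVT"
    df["delta_m"] = df["delta_beta"]
    df["significant"] = df["q"] < 0.1
    df["direction"] = np.where(
        df["delta_beta"].abs() <= 0.125,
        "none",
        np.where(df["delta_beta"] > 0, "hyper", "hypo"),
    )
    return df


def _manifest(entries):
    """entries: probe -> (gene_field, dist)"""
    return pd.DataFrame(
        {
            "UCSC_RefGene_Name": [v[0] for v in entries.values()],
            "DIST_TSS": [v[1] for v in entries.values()],
            "IMPRINT": "",
        },
        index=pd.Index(entries.keys(), name="IlmnID"),
    )


class TestGeneCalls:
    def test_any_qualifying_probe_rule(self):
        dm = _dm_frame([("p1", 0.3, 0.01), ("p2", 0.15, 0.01)])
        man = _manifest({"p1": ("GA", 100), "p2": ("GA", 100)})
        out = call_genes(dm, man)
        assert out.loc[out["gene"] == "GA", "call"].item() == "hyper"

    def test_mixed_directions_are_ambiguous(self):
        dm = _dm_frame([("p1", 0.3, 0.01), ("p2", -0.2, 0.01)])
        man = _manifest({"p1": ("GA", 100), "p2": ("GA", 100)})
        out = call_genes(dm, man)
        assert out["call"].item() == "ambiguous"

    def test_below_threshold_probes_do_not_call(self):
        dm = _dm_frame([("p1", 0.05, 0.01), ("p2", -0.10, 0.01)])
        man = _manifest({"p1": ("GA", 100), "p2": ("GA", 100)})
        assert call_genes(dm, man)["call"].item() == "none"

    def test_boundary_delta_beta_excluded(self):
        dm = _dm_frame([("p1", 0.125, 0.001)])
        man = _manifest({"p1": ("GA", 100)})
        assert call_genes(dm, man)["call"].item() == "none"

    def test_significance_and_magnitude_both_required(self):
        dm = _dm_frame([("p1", 0.4, 0.5)])  # large Δβ, not significant
        man = _manifest({"p1": ("GA", 100)})
        assert call_genes(dm, man)["call"].item() == "none"

    def test_multigene_probe_contributes_to_all_genes(self):
        dm = _dm_frame([("p1", 0.3, 0.01)])
        man = _manifest({"p1": ("GA;GB", 100)})
        out = call_genes(dm, man).set_index("gene")
        assert out.loc["GA", "call"] == "hyper" and out.loc["GB", "call"] == "hyper"

    def test_unannotated_probe_ignored(self):
        dm = _dm_frame([("p1", 0.3, 0.01), ("p2", 0.3, 0.01)])
        man = _manifest({"p1": ("GA", 100), "p2": ("", 100)})
        assert set(call_genes(dm, man)["gene"]) == {"GA"}


class TestTssProfile:
    def test_hand_counted_frequencies(self):
        dm = _dm_frame(
            [("p1", 0.3, 0.01), ("p2", 0.05, 0.5), ("p3", 0.05, 0.5), ("p4", 0.05, 0.5)]
        )
        man = _manifest(
            {"p1": ("GA", 50), "p2": ("GB", 150), "p3": ("GC", 450), "p4": ("GD", 950)}
        )
        prof = tss_profile(dm, man, "hyper")
        assert prof.total_in_window == 4
        np.testing.assert_allclose(prof.frequencies[0], 0.25)
        assert prof.frequencies[1:].sum() == 0.0
        assert len(prof.frequencies) == 10

    def test_no_dm_probes_gives_zero_frequencies(self):
        dm = _dm_frame([("p1", 0.01, 0.9)])
        man = _manifest({"p1": ("GA", 500)})
        prof = tss_profile(dm, man, "hypo")
        assert prof.frequencies.sum() == 0.0

    def test_empty_window_flagged_as_null(self):
        dm = _dm_frame([("p1", 0.3, 0.01)])
        man = _manifest({"p1": ("GA", 3000)})
        prof = tss_profile(dm, man, "hyper")
        assert prof.frequencies is None and prof.total_in_window == 0
        assert len(prof.scatter) == 1  # still in the 5 kbp scatter

    def test_bin_width_option(self):
        dm = _dm_frame([("p1", 0.3, 0.01)])
        man = _manifest({"p1": ("GA", 150)})
        prof = tss_profile(dm, man, "hyper", bin_width=200)
        assert len(prof.frequencies) == 5

    def test_planted_cc_hypermethylation_dominates_every_bin(self, small_dataset):
        """Choriocarcinoma plants mostly hypermethylation, so the hyper
        frequency exceeds the hypo frequency in each TSS bin."""
        manifest, bm, _, _ = small_dataset
        dm = dm_ttest_contrast(bm, "CCvsVT")
        hyper = tss_profile(dm, manifest, "hyper")
        hypo = tss_profile(dm, manifest, "hypo")
        assert (hyper.frequencies > hypo.frequencies).all()


class TestNullCalibration:
    def test_no_planted_effects_controls_fdr(self):
        """Zero-effect simulation: the q<0.1 discovery proportion stays at
        or below the nominal 10%."""
        from gtdmeth.config import SimulationConfig
        from gtdmeth.simulate import generate_beta, generate_manifest

        cfg = SimulationConfig(
            n_probes=4000,
            n_genes=400,
            seed=13,
            group_median_beta={g: 0.4 for g in ("VT", "PLA", "MOLE", "CC")},
            frac_dm_probes=0.0,
            frac_imprinted_maternal=0.0,
            frac_imprinted_paternal=0.0,
        )
        man = generate_manifest(cfg)
        bm = generate_beta(cfg, man)
        dm = dm_ttest_contrast(bm, "CCvsVT")
        assert dm["significant"].mean() <= 0.1
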