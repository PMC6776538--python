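"""Eq.-(1) decomposition: fold changes, expressing fractions, rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trisect import (BurstParams, classify_dosage, classify_expression_level,
                     compare_fractions, decompose_genes,
                     expected_fraction_expressing, expected_truncated_mean,
                     expected_zero_probability, fold_changes,
                     fraction_expressing, hyperbola_fit, is_expressed,
                     simulate_allele_counts, stratify_by_expression)


class TestClosedForms:
    def test_zero_probability(self):
        assert expected_zero_probability(0.1, 10) == pytest.approx((1 / 11) ** 0.1)

    def test_expressing_fraction_ratio_example(self):
        """p0 = 0.9 gives R2 = 0.19, R3 = 0.271, ratio 1.4263."""
        f = np.log(0.9) / np.log(1 / 11)       # f with b=10 such that p0=0.9
        assert expected_fraction_expressing(f, 10, 2) == pytest.approx(0.19)
        assert expected_fraction_expressing(f, 10, 3) == pytest.approx(0.271)
        ratio = (expected_fraction_expressing(f, 10, 3) /
                 expected_fraction_expressing(f, 10, 2))
        assert ratio == pytest.approx(1.4263, abs=1e-4)

    def test_truncated_mean_consistency(self):
        # R_k * sbar_k == k*f*b exactly
        for k in (2, 3):
            prod = (expected_fraction_expressing(0.3, 8, k) *
                    expected_truncated_mean(0.3, 8, k))
            assert prod == pytest.approx(k * 0.3 * 8)


class TestFoldChanges:
    def test_identity_is_exact(self):
        """fc_bulk == (R3/R2) * fc_sc to 1e-9 on arbitrary data."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.negative_binomial(0.4, 0.1, 500)
            t = rng.negative_binomial(0.4, 0.08, 400)
            if d.sum() == 0 or t.sum() == 0:
                continue
            r = fold_changes(d, t)
            assert abs(r["fc_bulk"] - r["r_ratio"] * r["fc_sc"]) < 1e-9

    def test_identical_distributions_give_unity(self):
        v = np.array([0, 1, 2, 3, 0, 5])
        r = fold_changes(v, v)
        assert r["fc_bulk"] == pytest.approx(1.0)
        assert r["fc_sc"] == pytest.approx(1.0)
        assert r["r_ratio"] == pytest.approx(1.0)

    def test_bursty_gene_matches_closed_forms(self):
        """f=0.1, b=10: fc_bulk -> 1.5, fc_sc -> 1.114, r_ratio -> 1.347."""
        params = BurstParams(0.1, 10)
        n = 200_000
        d = simulate_allele_counts(params, 2, n, seed=1).sum(axis=1)
        t = simulate_allele_counts(params, 3, n, seed=2).sum(axis=1)
        r = fold_changes(d, t)
        assert r["fc_bulk"] == pytest.approx(1.5, abs=0.03)
        assert r["fc_sc"] == pytest.approx(1.114, abs=0.02)
        assert r["r_ratio"] == pytest.approx(1.347, abs=0.02)
        assert abs(r["fc_bulk"] - r["r_ratio"] * r["fc_sc"]) < 1e-9

    def test_all_cells_expressing_collapses_to_bulk(self):
        rng = np.random.default_rng(1)
        d = rng.poisson(50, 1000) + 1
        t = rng.poisson(75, 1000) + 1
        r = fold_changes(d, t)
        assert r["r2"] == 1.0 and r["r3"] == 1.0
        assert r["fc_bulk"] == pytest.approx(r["fc_sc"])

    def test_zero_diploid_mean_flagged(self):
        r = fold_changes(np.zeros(10), np.ones(10))
        assert r["flagged"] and np.isnan(r["fc_bulk"])

    def test_fraction_expressing_requires_cells(self):
        with pytest.raises(ValueError):
            fraction_expressing(np.array([]))


class TestClassifications:
    @pytest.mark.parametrize("fc,expected", [(1.5, "sensitive"),
                                             (1.21, "sensitive"),
                                             (1.0, "insensitive"),
                                             (0.81, "insensitive"),
                                             (0.5, "other"), (1.2, "other")])
    def test_dosage_classes(self, fc, expected):
        assert classify_dosage(fc) == expected

    def test_dosage_requires_positive_fc(self):
        with pytest.raises(ValueError):
            classify_dosage(0.0)

    @pytest.mark.parametrize("x,expected", [(2.9, "low"), (3.0, "medium"),
                                            (15.0, "medium"), (15.1, "high")])
    def test_expression_classes(self, x, expected):
        assert classify_expression_level(x) == expected


class TestIsExpressed:
    def _obs(self, n_cells, rpsm):
        return pd.DataFrame({"cell_id": [f"c{i}" for i in range(n_cells)],
                             "gene_id": "g", "coverage": 30,
                             "rpsm": [rpsm] * n_cells})

    def test_gene_usability_boundary(self):
        _, usable9 = is_expressed(self._obs(9, 25.0))
        _, usable10 = is_expressed(self._obs(10, 25.0))
        assert not usable9.get("g", False)
        assert usable10["g"]

    def test_rpsm_threshold(self):
        flags, usable = is_expressed(self._obs(20, 19.9))
        assert flags.empty and usable.empty

    def test_droplet_preset(self):
        obs = pd.DataFrame({"cell_id": [f"c{i}" for i in range(60)],
                            "gene_id": "g", "coverage": 6, "rpsm": 1.0})
        flags, usable = is_expressed(obs, mode="droplet")
        assert usable["g"]          # 60 cells > 50, 6 reads > 5
        flags2, usable2 = is_expressed(obs.assign(coverage=5), mode="droplet")
        assert flags2.empty


class TestCompareFractions:
    def test_equal_fractions_give_p_one(self):
        r = np.linspace(0.1, 0.9, 20)
        with pytest.warns(UserWarning):
            out = compare_fractions(r, r)
        assert out["pvalue"] == 1.0

    def test_bursty_genes_have_higher_r3(self):
        """Low-frequency genes: R3 > R2, detected at n >= 50 genes."""
        rng = np.random.default_rng(0)
        f = np.exp(rng.uniform(np.log(0.02), np.log(0.2), 60))
        b = np.exp(rng.uniform(np.log(5), np.log(30), 60))
        n = 300
        r2 = np.empty(60)
        r3 = np.empty(60)
        for i in range(60):
            p = 1 / (1 + b[i])
            r2[i] = (rng.negative_binomial(f[i], p, (n, 2)).sum(1) > 0).mean()
            r3[i] = (rng.negative_binomial(f[i], p, (n, 3)).sum(1) > 0).mean()
        out = compare_fractions(r2, r3)
        assert out["pvalue"] < 0.05
        assert np.median(r3 - r2) > 0

    def test_type_one_error_calibrated_under_null(self):
        """Paired test on exchangeable draws yields ~uniform p-values."""
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(300):
            a = rng.random(12)
            b = rng.random(12)
            pvals.append(compare_fractions(a, b)["pvalue"])
        # exact-test p-values are discrete; KS against uniform is loose
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        assert np.mean(np.array(pvals) < 0.05) < 0.10

    def test_minimum_pairs(self):
        with pytest.raises(ValueError):
            compare_fractions([0.1] * 5, [0.2] * 5)


class TestHyperbola:
    def test_exact_points_give_perfect_anticorrelation(self):
        fc_sc = np.linspace(1.0, 1.5, 15)
        summary = pd.DataFrame({"r_ratio": 1.5 / fc_sc, "fc_sc": fc_sc})
        out = hyperbola_fit(summary)
        assert out["rho"] == pytest.approx(-1.0)
        assert np.allclose(out["predicted_r_ratio"], summary["r_ratio"])

    def test_degenerate_input_rejected(self):
        summary = pd.DataFrame({"r_ratio": [1.2] * 12, "fc_sc": [1.1] * 12})
        with pytest.raises(ValueError):
            hyperbola_fit(summary)

    def test_too_few_genes_rejected(self):
        summary = pd.DataFrame({"r_ratio": [1.0, 1.1], "fc_sc": [1.5, 1.4]})
        with pytest.raises(ValueError):
            hyperbola_fit(summary)


class TestPopulationDecomposition:
    @staticmethod
    def _summary(sim):
        return decompose_genes(sim.expression, sim.truth.cell_labels)

    def test_supernumerary_genes_follow_the_hyperbola(self, mosaic_sim):
        summary = self._summary(mosaic_sim)
        out = hyperbola_fit(summary)
        assert out["rho"] < -0.3 and out["pvalue"] < 1e-3

    def test_disomic_control_centres_at_one(self):
        """On a control chromosome both ratios centre at 1 (sign test)."""
        from trisect import SimConfig, simulate_population
        cfg = SimConfig(n_genes=5, n_genes_control=80, n_cells_diploid=300,
                        n_cells_trisomic=300, rng_seed=13)
        sim = simulate_population(cfg)
        control_genes = [g for g in sim.expression.columns if g.startswith("g1_")]
        summary = decompose_genes(sim.expression, sim.truth.cell_labels,
                                  genes=control_genes)
        for col in ("r_ratio", "fc_bulk"):
            vals = summary[col].dropna()
            assert abs(vals.median() - 1.0) < 0.05
            vals = vals[vals != 1.0]        # sign test discards exact ties
            n_hi = int((vals > 1).sum())
            p = stats.binomtest(n_hi, len(vals), 0.5).pvalue
            assert p > 0.01, f"{col} off-centre: {vals.median():.3f}"

    def test_r_ratio_decreases_with_expression_class(self, mosaic_sim):
        """Dosage imbalance shifts from cell fraction to per-cell FC as
        expression grows: median R3/R2 is highest for low-expressed genes."""
        summary = self._summary(mosaic_sim)
        out = stratify_by_expression(summary)
        med = {c: out["classes"][c]["median_r_ratio"]
               for c in out["classes"]}
        assert med["low"] > med["medium"] > med["high"]
        assert med["high"] == pytest.approx(1.0, abs=0.05)
        fc = {c: out["classes"][c]["median_fc_sc"] for c in out["classes"]}
        assert fc["high"] > fc["low"]

    def test_single_class_reports_medians_only(self):
        summary = pd.DataFrame({"expression_class": ["low"] * 5,
                                "r_ratio": [1.3] * 5, "fc_sc": [1.1] * 5})
        out = stratify_by_expression(summary)
        assert list(out["classes"]) == ["low"]
        assert out["tests"] == {}

    def test_identity_holds_for_every_gene(self, mosaic_sim):
        summary = self._summary(mosaic_sim)
        ok = summary.dropna(subset=["fc_bulk", "fc_sc", "r_ratio"])
        err = (ok["fc_bulk"] - ok["r_ratio"] * ok["fc_sc"]).abs()
        assert (err < 1e-9).all()

    def test_requires_both_ploidies(self, mosaic_sim):
        labels = pd.Series("diploid", index=mosaic_sim.expression.index)
        with pytest.raises(ValueError):
            decompose_genes(mosaic_sim.expression, labels)
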