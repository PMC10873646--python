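"""ddCt quantification, NB differential expression and enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sparkquant import synthetic
from sparkquant.expression import (
    compare_contrasts,
    ddct,
    de_test,
    enrichment_test,
    size_factors,
)


class TestDdct:
    def _table(self, fc, noise=0.0, seed=0):
        return synthetic.generate_ct_table({"G": fc}, ct_noise_sd=noise, seed=seed)

    def test_no_change_gives_unity(self):
        res = ddct(self._table(1.0), ["G"], "ACTB", "control")
        row = res.table.iloc[0]
        assert row["ddct"] == pytest.approx(0.0, abs=1e-9)
        assert row["relative_expression"] == pytest.approx(1.0)
        assert row["percent_change"] == pytest.approx(0.0, abs=1e-6)

    def test_ddct_one_is_50pct_decrease(self):
        res = ddct(self._table(0.5), ["G"], "ACTB", "control")
        assert res.percent_decrease("G") == pytest.approx(50.0, abs=1e-6)

    def test_noisy_fold_change_recovered(self):
        res = ddct(self._table(0.16, noise=0.1, seed=5), ["G"], "ACTB", "control")
        assert res.percent_decrease("G") == pytest.approx(84.0, abs=3.0)
        assert res.table["p_value"].iloc[0] < 0.01

    def test_missing_reference_rejected(self):
        tbl = self._table(0.5)
        with pytest.raises(ValueError, match="reference gene"):
            ddct(tbl, ["G"], "GAPDH", "control")


class TestSizeFactors:
    def test_scaling_a_library_scales_its_factor(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=(500, 4))
        counts = pd.DataFrame(base, columns=list("abcd"))
        counts["d"] = counts["d"] * 3
        sf = size_factors(counts)
        assert sf["d"] / sf["a"] == pytest.approx(3.0, rel=0.05)


class TestDeTest:
    def _design(self, counts):
        return {c: ("treated" if c.startswith("treated") else "control")
                for c in counts.columns}

    def test_identical_columns_give_zero_calls(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(200, 300)
        counts = pd.DataFrame({f"{c}_{i}": col for c in ("control", "treated")
                               for i in (1, 2, 3)})
        res = de_test(counts, self._design(counts))
        assert np.allclose(res.table["log2fc"], 0.0)
        assert res.n_up == res.n_down == 0

    def test_label_swap_antisymmetry(self):
        gt = synthetic.CountsGroundTruth(n_genes=800, seed=3,
                                         de_lfc={"gene00005": 2.0, "gene00010": -2.0})
        counts, _ = synthetic.generate_counts(gt)
        design = self._design(counts)
        fwd = de_test(counts, design, test_condition="treated", control_condition="control")
        rev = de_test(counts, design, test_condition="control", control_condition="treated")
        assert np.allclose(fwd.table["log2fc"], -rev.table["log2fc"])
        assert np.allclose(fwd.table["p_value"], rev.table["p_value"])
        assert fwd.genes("up") == rev.genes("down")
        assert fwd.genes("down") == rev.genes("up")

    def test_call_invariant_matches_thresholds(self):
        gt = synthetic.CountsGroundTruth(
            n_genes=2000, seed=4,
            de_lfc={f"gene{i:05d}": s * 2.0 for i, s in
                    zip(range(0, 40), itertools.cycle([1, -1]))})
        counts, _ = synthetic.generate_counts(gt)
        res = de_test(counts, self._design(counts))
        t = res.table
        up = (t["p_value"] < 0.01) & (t["log2fc"] >= 0.58) & (t["fdr"] < 0.1)
        down = (t["p_value"] < 0.01) & (t["log2fc"] <= -0.58) & (t["fdr"] < 0.1)
        assert ((t["call"] == "up") == up).all()
        assert ((t["call"] == "down") == down).all()

    def test_bh_fdr_monotone_in_p_rank(self):
        gt = synthetic.CountsGroundTruth(n_genes=500, seed=5)
        counts, _ = synthetic.generate_counts(gt)
        t = de_test(counts, self._design(counts)).table.sort_values("p_value")
        assert (np.diff(t["fdr"]) >= -1e-12).all()

    def test_power_at_high_depth(self):
        """Truth genes at |log2FC|=2 and mean >= 500 are recalled >= 95%."""
        spikes = {f"gene{i:05d}": (2.0 if i % 2 else -2.0) for i in range(40)}
        gt = synthetic.CountsGroundTruth(n_genes=4000, dispersion=0.05,
                                         de_min_mean=500.0, de_lfc=spikes, seed=6)
        counts, truth = synthetic.generate_counts(gt)
        res = de_test(counts, self._design(counts))
        called = res.genes("up") | res.genes("down")
        recall = len(called & set(spikes)) / len(spikes)
        assert recall >= 0.95

    def test_wald_p_matches_exact_nb_enumeration(self):
        """On a 2v2 toy at fixed dispersion, the Wald p agrees with the
        exact null distribution of the statistic, computed by enumerating
        per-condition sums (sum of n iid NB(mu, d) ~ NB(n*mu, d/n))."""
        disp, prior = 0.05, 0.5
        c_ctrl, c_trt = [90, 110], [130, 150]
        counts = pd.DataFrame({f"bg{i}": [100 + i] * 4 for i in range(30)},
                              index=["control_1", "control_2", "treated_1", "treated_2"]).T
        counts.loc["focal"] = c_ctrl + c_trt
        res = de_test(counts.astype(int), self._design(counts), dispersion=disp)
        p_wald = float(res.table.loc["focal", "p_value"])

        def zstat(m1, m2):
            lfc = np.log2((m1 + prior) / (m2 + prior))
            se = np.sqrt((1 / np.clip(m1, prior, None) + disp) / 2
                         + (1 / np.clip(m2, prior, None) + disp) / 2)
            return lfc * np.log(2.0) / se

        mu0 = (sum(c_ctrl) + sum(c_trt)) / 4.0
        z_obs = zstat(np.mean(c_trt), np.mean(c_ctrl))
        r = 2.0 / disp
        s = np.arange(0, 1200)
        pmf = stats.nbinom.pmf(s, r, r / (r + 2 * mu0))
        Z = zstat(s[:, None] / 2.0, s[None, :] / 2.0)
        p_exact = float((pmf[:, None] * pmf[None, :])[np.abs(Z) >= abs(z_obs) - 1e-12].sum())
        assert p_wald == pytest.approx(p_exact, rel=0.10)

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"control_1": [5, 8], "treated_1": [7, 9],
                               "treated_2": [6, 10]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="replicates"):
            de_test(counts, {"control_1": "control", "treated_1": "treated",
                             "treated_2": "treated"})

    def test_non_integer_counts_rejected(self):
        counts = pd.DataFrame(np.full((3, 4), 1.5),
                              columns=["control_1", "control_2", "treated_1", "treated_2"])
        with pytest.raises(ValueError, match="integer"):
            de_test(counts, self._design(counts))


class TestCompareContrasts:
    def _three_results(self, seed=0):
        counts, design, truth = synthetic.generate_study_counts(
            n_genes=3000, n_responsive_up=300, n_responsive_down=240,
            n_ps_up=11, n_ps_down=11, seed=seed)
        pairs = {"condensed_vs_control": ("condensed", "control"),
                 "diffuse_vs_control": ("diffuse", "control"),
                 "condensed_vs_diffuse": ("condensed", "diffuse")}
        return {n: de_test(counts, design, test_condition=a, control_condition=b)
                for n, (a, b) in pairs.items()}, truth

    def test_identical_contrasts_full_intersection(self):
        res, _ = self._three_results()
        one = res["condensed_vs_control"]
        comp = compare_contrasts({"a": one, "b": one})
        assert comp.intersections["a&b_up"] == len(comp.up["a"])

    def test_ps_genes_isolated_by_third_contrast(self):
        res, truth = self._three_results(seed=2)
        comp = compare_contrasts(res, primary="condensed_vs_control",
                                 ps_contrast="condensed_vs_diffuse")
        ps_up_true = set(truth.index[truth["ps_lfc"] > 0])
        assert ps_up_true <= comp.up["condensed_vs_diffuse"]
        # PS-regulated genes are a small share of the responsive set
        assert comp.further_enhanced_fraction_pct < 10.0

    def test_mismatched_universe_rejected(self):
        res, _ = self._three_results()
        a = res["condensed_vs_control"]
        b = res["diffuse_vs_control"]
        b_small = type(b)(table=b.table.iloc[:-5], test_condition=b.test_condition,
                          control_condition=b.control_condition, thresholds=b.thresholds)
        with pytest.raises(ValueError, match="universe"):
            compare_contrasts({"a": a, "b": b_small})


class TestEnrichment:
    def test_full_overlap_boundary_p_is_one(self):
        uni = {f"g{i}" for i in range(50)}
        res = enrichment_test(uni, {"all": uni}, uni)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_empty_deg_set_gives_p_one(self):
        uni = {f"g{i}" for i in range(30)}
        res = enrichment_test(set(), {"s": set(list(uni)[:10])}, uni)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_matches_bruteforce_tail_enumeration(self):
        """p equals the hypergeometric tail summed term by term."""
        from math import comb

        M, K, n, k = 20, 6, 8, 4  # universe, set, deg, overlap
        uni = [f"g{i}" for i in range(M)]
        gs = set(uni[:K])
        deg = set(uni[K - k:K]) | set(uni[K: K + (n - k)])
        assert len(deg & gs) == k
        res = enrichment_test(deg, {"s": gs}, uni)
        brute = sum(comb(K, j) * comb(M - K, n - j) for j in range(k, min(K, n) + 1)) / comb(M, n)
        assert res["p_value"].iloc[0] == pytest.approx(brute, rel=1e-9)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            enrichment_test({"a"}, {"s": {"zz"}}, {"a", "b"})
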