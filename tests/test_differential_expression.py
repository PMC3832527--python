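import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

from tagdge.differential_expression import (
    bh_adjust,
    consistency_filter,
    exclude_genes_by_terms,
    fit_condition_means,
    lrt_test,
    run_de_pipeline,
)
from tagdge.dispersion_model import estimate_gene_dispersion
from tagdge.io_formats import ExpressionMatrix, RunConfig
from tagdge.synthetic_data import SimulationParams, simulate_counts

from .conftest import TWO_BY_TWO_DESIGN, make_matrix


def with_dispersion(matrix, phi):
    """Dispersion estimates with the smoothed value forced to phi."""
    est = estimate_gene_dispersion(matrix)
    est.table["smoothed_dispersion"] = float(phi)
    return est


class TestExclusion:
    def test_empty_term_list_is_identity(self, random_counts):
        m = ExpressionMatrix(random_counts, dict(TWO_BY_TWO_DESIGN))
        g2g = pd.DataFrame({"gene_id": ["g0"], "term": ["GO:1"]})
        out = exclude_genes_by_terms(m, g2g, [])
        assert out.n_genes == m.n_genes

    def test_annotated_genes_removed(self):
        m = make_matrix({g: [1, 2, 3, 4] for g in "abcde"})
        g2g = pd.DataFrame(
            {"gene_id": ["a", "c", "zz"], "term": ["GO:IMM", "GO:IMM", "GO:IMM"]}
        )
        out = exclude_genes_by_terms(m, g2g, ["GO:IMM"])
        assert list(out.counts.index) == ["b", "d", "e"]


class TestConditionMeans:
    def test_worked_example(self, worked_matrix):
        assert fit_condition_means(worked_matrix, "g1") == (20.0, 10.0, 15.0)

    def test_offset_scaling(self):
        m = make_matrix({"g": [40, 40, 10, 10]}, size_factors=[2, 2, 1, 1.0])
        lam_g, lam_m, _ = fit_condition_means(m, "g")
        assert lam_g == 20.0
        assert lam_m == 10.0

    def test_matches_numerical_likelihood_maximisation(self):
        """The closed-form means agree with brute-force maximisation of
        the Poisson log-likelihood on the normalised counts."""
        rng = np.random.default_rng(12)
        for _ in range(5):
            y = rng.poisson(30, size=4)
            s = rng.uniform(0.5, 2.0, size=4)
            m = make_matrix({"g": y.tolist()}, size_factors=s)
            lam_g, lam_m, lam0 = fit_condition_means(m, "g")
            z = y / s

            def negll(lams, z=z):
                mu = np.concatenate(
                    [np.full(2, lams[0]), np.full(2, lams[1])]
                )
                return -(z * np.log(mu) - mu).sum()

            res = minimize(
                negll,
                x0=[10.0, 10.0],
                bounds=[(1e-9, None)] * 2,
                method="L-BFGS-B",
                options={"ftol": 1e-14, "gtol": 1e-12},
            )
            np.testing.assert_allclose([lam_g, lam_m], res.x, rtol=1e-5)
            assert lam0 == pytest.approx(z.mean())


class TestLRT:
    def test_identical_groups_null(self):
        m = make_matrix({"g": [12, 12, 12, 12]})
        r = lrt_test(m, with_dispersion(m, 1.0))
        assert r["lrt_stat"].loc["g"] == 0.0
        assert r["p_value"].loc["g"] == 1.0

    def test_worked_example(self, worked_matrix):
        r = lrt_test(worked_matrix, with_dispersion(worked_matrix, 1.0))
        assert r["lrt_stat"].loc["g1"] == pytest.approx(6.796, abs=1e-3)
        assert r["p_value"].loc["g1"] == pytest.approx(0.0091, abs=1e-3)

    def test_statistic_scales_inversely_with_dispersion(self, worked_matrix):
        r2 = lrt_test(worked_matrix, with_dispersion(worked_matrix, 2.0))
        assert r2["lrt_stat"].loc["g1"] == pytest.approx(6.796 / 2, abs=1e-3)
        assert r2["p_value"].loc["g1"] == pytest.approx(0.065, abs=1e-3)

    def test_monotone_decreasing_in_dispersion(self, worked_matrix):
        stats_by_phi = [
            lrt_test(worked_matrix, with_dispersion(worked_matrix, phi))[
                "lrt_stat"
            ].loc["g1"]
            for phi in (1.0, 1.5, 2.0, 4.0)
        ]
        assert all(a > b for a, b in zip(stats_by_phi, stats_by_phi[1:]))

    def test_zero_count_gene_untestable(self):
        m = make_matrix({"a": [0, 0, 0, 0], "b": [20, 20, 10, 10]})
        est = estimate_gene_dispersion(m)
        est.table["smoothed_dispersion"] = np.where(est.table["testable"], 1.0, np.nan)
        r = lrt_test(m, est)
        assert not r["testable"].loc["a"]
        assert np.isnan(r["p_value"].loc["a"])
        assert np.isfinite(r["p_value"].loc["b"])

    def test_scale_equivariance(self):
        """Multiplying one sample's counts and size factor by a constant
        leaves every statistic unchanged."""
        rng = np.random.default_rng(3)
        counts = {f"g{i}": rng.poisson(40, 4).tolist() for i in range(30)}
        m1 = make_matrix(counts)
        scaled = {g: [3 * c[0], c[1], c[2], c[3]] for g, c in counts.items()}
        m2 = make_matrix(scaled, size_factors=[3, 1, 1, 1.0])
        r1 = lrt_test(m1, with_dispersion(m1, 1.3))
        r2 = lrt_test(m2, with_dispersion(m2, 1.3))
        np.testing.assert_allclose(r1["lrt_stat"], r2["lrt_stat"], rtol=1e-10)
        np.testing.assert_allclose(r1["p_value"], r2["p_value"], rtol=1e-10)


class TestBH:
    def test_all_ones_no_rejection(self):
        q, rej = bh_adjust([1.0] * 10, alpha=0.05)
        assert not rej.any()
        assert (q == 1.0).all()

    def test_hand_computed_step_up(self):
        q, rej = bh_adjust([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        np.testing.assert_allclose(q, 0.04)
        assert rej.all()

    def test_boundary_uses_lessequal(self):
        q, rej = bh_adjust([0.05], alpha=0.05)
        assert rej[0]

    def test_nan_passthrough(self):
        q, rej = bh_adjust([0.01, np.nan, 0.5], alpha=0.05)
        assert np.isnan(q[1]) and not rej[1]
        # m counts only the two defined p-values
        assert q[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([1.5])


class TestConsistencyFilter:
    def _results(self, matrix, direction):
        r = lrt_test(matrix, with_dispersion(matrix, 1.0))
        r["q_value"] = 0.01
        r["direction"] = direction
        return r

    def test_concordant_gene_retained(self):
        m = make_matrix({"g": [10, 12, 5, 6]})
        out = consistency_filter(self._results(m, "up_in_G"), m)
        assert out["consistent"].loc["g"]
        assert out["de"].loc["g"]

    def test_discordant_gene_filtered(self):
        m = make_matrix({"g": [10, 4, 5, 6]})
        out = consistency_filter(self._results(m, "up_in_G"), m)
        assert not out["consistent"].loc["g"]
        assert not out["de"].loc["g"]

    def test_pairwise_mode_is_weaker(self):
        # replicate-wise 10>5 and 4>3 hold, but min(G)=4 <= max(M)=5
        m = make_matrix({"g": [10, 4, 5, 3]})
        strict = consistency_filter(self._results(m, "up_in_G"), m, mode="minmax")
        pairwise = consistency_filter(self._results(m, "up_in_G"), m, mode="pairwise")
        assert not strict["de"].loc["g"]
        assert pairwise["de"].loc["g"]

    def test_filter_never_increases_false_discovery_proportion(self):
        """Over repeated small simulations, removing replicate-discordant
        genes can only shrink the false-discovery proportion."""
        for seed in range(30):
            p = SimulationParams(
                n_genes=400, seed=seed, de_fraction=0.1, dispersion_noise_sd=0.3
            )
            m, truth = simulate_counts(p)
            res, _ = run_de_pipeline(m, RunConfig())
            pre = res["direction"] != "none"
            post = res["de"]
            is_false = ~truth["is_de"]
            fdp_pre = (pre & is_false).sum() / max(pre.sum(), 1)
            fdp_post = (post & is_false).sum() / max(post.sum(), 1)
            assert fdp_post <= fdp_pre + 1e-12


class TestPipeline:
    def test_null_data_yields_no_discoveries(self):
        p = SimulationParams(n_genes=5000, seed=31, de_fraction=0.0)
        m, _ = simulate_counts(p)
        _, summary = run_de_pipeline(m, RunConfig())
        assert summary["n_pre_filter_de"] <= 5

    def test_power_and_bookkeeping(self):
        p = SimulationParams(n_genes=5000, seed=32, de_fraction=0.05)
        m, truth = simulate_counts(p)
        res, summary = run_de_pipeline(m, RunConfig())
        assert (
            summary["n_post_filter_de"]
            == summary["n_pre_filter_de"] - summary["n_filtered"]
        )
        assert summary["n_up_in_G"] + summary["n_up_in_M"] == summary["n_pre_filter_de"]
        true_de = set(truth.index[truth["is_de"]])
        called = set(res.index[res["de"]])
        recall = len(called & true_de) / len(true_de)
        assert recall > 0.7

    def test_exclusion_reduces_testing_burden(self):
        p = SimulationParams(n_genes=500, seed=33)
        m, _ = simulate_counts(p)
        genes = list(m.counts.index)
        g2g = pd.DataFrame({"gene_id": genes[:40], "term": ["GO:IMM"] * 40})
        cfg = RunConfig(excluded_go_terms=("GO:IMM",))
        _, summary = run_de_pipeline(m, cfg, gene2go=g2g)
        assert summary["n_excluded"] == 40
        assert summary["n_input"] == 500
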