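"""Mixed-model association: filters, kinship, REML fits, GWAS plumbing."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from poolsel.datatypes import AssociationResult
from poolsel.lmm import (
    LMMScanner,
    collapse_to_ld_groups,
    compute_kinship,
    filter_variants,
    fit_lmm_single,
    run_gwas,
)

from conftest import make_panel


def random_panel(n, m, seed, maf_lo=0.1, replicon="chromosome"):
    rng = np.random.default_rng(seed)
    p = rng.uniform(maf_lo, 0.5, m)
    calls = (rng.random((n, m)) < p).astype(float)
    # avoid monomorphic columns
    calls[0, calls.sum(axis=0) == 0] = 1.0
    calls[0, calls.sum(axis=0) == n] = 0.0
    return make_panel(calls, replicon=replicon)


class TestFilterVariants:
    def test_rare_variant_removed(self):
        calls = np.zeros((86, 2))
        calls[:3, 0] = 1.0  # MAF 3/86 ~ 0.035 < 0.05
        calls[:10, 1] = 1.0
        panel = make_panel(calls)
        out = filter_variants(panel)
        assert list(out.variant_ids) == [panel.variant_ids[1]]

    def test_maf_007_retained_and_boundaries(self):
        calls = np.zeros((100, 3))
        calls[:7, 0] = 1.0  # MAF 0.07 -> kept
        calls[:5, 1] = 1.0  # MAF exactly 0.05 -> kept (not < 0.05)
        calls[:30, 2] = 1.0
        panel = make_panel(calls)
        out = filter_variants(panel)
        assert len(out.variant_ids) == 3

    def test_missingness_removal(self):
        calls = np.zeros((20, 2))
        calls[:8, 0] = 1.0
        calls[:8, 1] = 1.0
        calls[:5, 1] = np.nan  # 25% missing > 0.2
        panel = make_panel(calls)
        out = filter_variants(panel)
        assert len(out.variant_ids) == 1

    def test_empty_result_rejected(self):
        calls = np.zeros((86, 1))
        calls[0, 0] = 1.0
        with pytest.raises(ValueError):
            filter_variants(make_panel(calls))


class TestKinship:
    def test_identical_strains_share_diagonal(self):
        panel = random_panel(10, 50, seed=1)
        calls = panel.calls.copy()
        calls.iloc[1] = calls.iloc[0]
        panel = make_panel(calls.to_numpy())
        k = compute_kinship(panel).matrix
        assert k.iloc[0, 1] == pytest.approx(k.iloc[0, 0], abs=1e-12)

    def test_psd_and_off_diagonal_shrinks(self):
        panel = random_panel(20, 5000, seed=2)
        k = compute_kinship(panel).matrix.to_numpy()
        assert np.linalg.eigvalsh(k).min() >= -1e-8
        off = k[~np.eye(20, dtype=bool)]
        assert np.abs(off).mean() < 0.08  # ~N(0, 1/sqrt(m)) scale

    def test_zero_variance_column_dropped(self):
        calls = np.column_stack([np.zeros(10), (np.arange(10) < 4).astype(float)])
        with pytest.warns(UserWarning, match="zero-variance"):
            compute_kinship(make_panel(calls))


def naive_reml_fit(y, x, k):
    """Direct O(n^3)-per-delta REML oracle with explicit matrix inverses."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])

    def profile(delta):
        h = k + delta * np.eye(n)
        hinv = np.linalg.inv(h)
        a = X.T @ hinv @ X
        b = X.T @ hinv @ y
        beta = np.linalg.solve(a, b)
        quad = float(y @ hinv @ y - b @ beta)
        npp = n - 2
        ll = 0.5 * (
            npp * np.log(npp / (2 * np.pi)) - npp - npp * np.log(quad)
            - np.linalg.slogdet(h)[1] - np.linalg.slogdet(a)[1]
        )
        return ll, beta, a, quad

    grid = np.logspace(-5, 5, 64)
    lls = [profile(d)[0] for d in grid]
    i = int(np.argmax(lls))
    lo, hi = np.log10(grid[max(i - 1, 0)]), np.log10(grid[min(i + 1, 63)])
    res = optimize.minimize_scalar(
        lambda t: -profile(10.0**t)[0], bounds=(lo, hi), method="bounded"
    )
    delta = 10.0**res.x
    ll, beta, a, quad = profile(delta)
    sigma_g2 = quad / (n - 2)
    se = np.sqrt(sigma_g2 * np.linalg.inv(a)[1, 1])
    wald = (beta[1] / se) ** 2
    return beta[1], se, stats.chi2.sf(wald, 1)


class TestFitLMM:
    def test_zero_kinship_reduces_to_ols(self):
        rng = np.random.default_rng(7)
        n = 40
        x = (rng.random(n) < 0.4).astype(float)
        y = 0.8 * x + rng.normal(0, 1, n)
        fit = fit_lmm_single(y, x, np.zeros((n, n)))
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta_ols
        s2 = resid @ resid / (n - 2)
        se_ols = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert fit.beta == pytest.approx(beta_ols[1], abs=1e-8)
        assert fit.se == pytest.approx(se_ols, abs=1e-8)
        p_ols = stats.chi2.sf((beta_ols[1] / se_ols) ** 2, 1)
        assert fit.p_value == pytest.approx(p_ols, abs=1e-8)

    def test_matches_naive_reml_oracle(self):
        rng = np.random.default_rng(11)
        panel = random_panel(20, 60, seed=11)
        k = compute_kinship(panel).matrix.to_numpy()
        g = panel.dosage()
        u = rng.multivariate_normal(np.zeros(20), 0.6 * k + 1e-9 * np.eye(20))
        for j in (0, 5, 17):
            y = 1.2 * g[:, j] + u + rng.normal(0, 0.7, 20)
            fit = fit_lmm_single(y, g[:, j], k)
            beta, se, p = naive_reml_fit(y, g[:, j], k)
            assert fit.beta == pytest.approx(beta, abs=1e-6)
            assert fit.se == pytest.approx(se, abs=1e-6)
            assert fit.p_value == pytest.approx(p, abs=1e-6)

    def test_vectorised_scan_matches_single_fits(self):
        panel = random_panel(30, 40, seed=3)
        k = compute_kinship(panel)
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 30)
        sc = LMMScanner(y, k)
        g = panel.dosage()
        tab = sc.fit_all(g, panel.variant_ids)
        for j in (0, 10, 39):
            f = sc.fit(g[:, j], panel.variant_ids[j])
            assert tab["beta"].iloc[j] == pytest.approx(f.beta, abs=1e-6)
            assert tab["p"].iloc[j] == pytest.approx(f.p_value, rel=1e-4)

    def test_constant_response_rejected(self):
        panel = random_panel(10, 5, seed=4)
        with pytest.raises(ValueError, match="degenerate"):
            fit_lmm_single(np.ones(10), panel.dosage()[:, 0],
                           compute_kinship(panel))

    def test_strain_relabelling_exchangeability(self):
        panel = random_panel(25, 50, seed=5)
        k = compute_kinship(panel).matrix.to_numpy()
        rng = np.random.default_rng(5)
        g = panel.dosage()[:, 3]
        y = g + rng.normal(0, 1, 25)
        fit = fit_lmm_single(y, g, k)
        perm = rng.permutation(25)
        fit_p = fit_lmm_single(y[perm], g[perm], k[np.ix_(perm, perm)])
        assert fit_p.beta == pytest.approx(fit.beta, abs=1e-8)
        assert fit_p.p_value == pytest.approx(fit.p_value, rel=1e-6)

    def test_power_monotone_in_effect_size(self):
        panel = random_panel(86, 100, seed=6)
        k = compute_kinship(panel)
        g = panel.dosage()
        rng = np.random.default_rng(6)
        j = int(np.argmin(np.abs(panel.maf() - 0.3)))
        mean_neglog = []
        for beta in (0.0, 0.75, 1.5):
            vals = []
            for _ in range(5):
                y = beta * g[:, j] + rng.normal(0, 0.5, 86)
                vals.append(-np.log10(fit_lmm_single(y, g[:, j], k).p_value))
            mean_neglog.append(np.mean(vals))
        assert mean_neglog[0] < mean_neglog[1] < mean_neglog[2]


class TestRunGwas:
    def test_response_times_replicon_table_count(self, tiny_experiment):
        sim = tiny_experiment
        w = sim.truth.true_fitness
        shifts = w.drop(columns=["A17"]).sub(w["A17"], axis=0)  # 5 mutants
        res = run_gwas(shifts, sim.genotypes, mode="shift")
        res += run_gwas(w[["A17"]], sim.genotypes, mode="fitness")
        assert len(res) == (5 + 1) * 3
        labels = {(r.response, r.replicon) for r in res}
        assert len(labels) == 18

    def test_deterministic_and_empty_response(self, tiny_experiment):
        sim = tiny_experiment
        w = sim.truth.true_fitness
        y = w[["m01"]]
        a = run_gwas(y, sim.genotypes)[0].table
        b = run_gwas(y, sim.genotypes)[0].table
        pd.testing.assert_frame_equal(a, b)
        assert run_gwas(w[[]], sim.genotypes) == []

    def test_all_missing_response_skipped(self, tiny_experiment):
        sim = tiny_experiment
        w = sim.truth.true_fitness.copy()
        w["dead_host"] = np.nan
        res = run_gwas(w[["dead_host"]], sim.genotypes)
        assert res == []


class TestCollapse:
    def _result(self, p_values, groups):
        tab = pd.DataFrame(
            {
                "beta": np.ones(len(p_values)),
                "se": np.ones(len(p_values)),
                "wald": np.ones(len(p_values)),
                "p": p_values,
                "converged": True,
                "ld_group": groups,
            },
            index=pd.Index([f"v{i}" for i in range(len(p_values))], name="variant"),
        )
        tab["rank"] = tab["p"].rank(method="min").astype(int)
        return AssociationResult("shift:m01", "chromosome", tab)

    def test_singleton_groups_identity(self):
        res = self._result([0.5, 0.01, 0.2], ["g1", "g2", "g3"])
        out = collapse_to_ld_groups(res)
        assert len(out.table) == 3
        assert out.table.loc["g2", "rank"] == 1

    def test_group_takes_minimum_p(self):
        res = self._result([1e-3, 1e-6, 0.9], ["g1", "g1", "g2"])
        out = collapse_to_ld_groups(res)
        assert out.table.loc["g1", "p"] == pytest.approx(1e-6)
        assert out.table.loc["g1", "representative"] == "v1"
        assert out.table.loc["g1", "members"] == ["v1", "v0"]

    def test_perfect_ld_members_share_p(self, tiny_experiment):
        sim = tiny_experiment
        y = sim.truth.true_fitness[["m01"]]
        res = run_gwas(y, sim.genotypes, replicons=["pSymA"])[0]
        joined = res.table.groupby("ld_group")["p"].agg(["min", "max", "count"])
        multi = joined[joined["count"] > 1]
        assert len(multi) > 0
        assert np.allclose(multi["min"], multi["max"], rtol=1e-9)

    def test_unmapped_variant_rejected(self):
        res = self._result([0.5, 0.2], ["g1", "g2"])
        ld = pd.Series({"v0": "g1"})  # v1 unmapped
        with pytest.raises(ValueError, match="not mapped"):
            collapse_to_ld_groups(res, ld)
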