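"""Mixed-model association: REML against a grid oracle, GLS against a dense
explicit-inverse oracle, OLS collapse, calibration and invariances."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from cnvrgwas.grm import add_ridge, compute_grm
from cnvrgwas.mlm import (
    AssociationResult,
    MixedModelSpec,
    VarianceComponents,
    _reml_loglik,
    bh_qvalues,
    eigendecompose,
    fit_null_reml,
    manhattan_qq_data,
    run_gwas,
    significance_threshold,
)
from cnvrgwas.mlm import test_cnvr as wald_test_cnvr
from cnvrgwas.types import Cnvr, CnvrType, GenotypeMatrix, GrmMatrix


def random_gm(rng, n, m, freq=0.1):
    """Random three-state genotype matrix, mostly losses, carrier freq ~freq."""
    carrier = rng.random((n, m)) < freq
    sign = np.where(rng.random((n, m)) < 0.9, -1, 1)
    codes = (carrier * sign).astype(np.int8)
    return GenotypeMatrix(
        sample_ids=[f"S{i:04d}" for i in range(n)],
        cnvr_ids=[f"R{j:05d}" for j in range(m)],
        codes=codes,
        frequencies=(codes != 0).sum(axis=0) / n,
    )


def simulate_trait(rng, grm, h2):
    """y with polygenic fraction h2 on the given GRM, total variance 1."""
    n = grm.n
    d, u = np.linalg.eigh(grm.values)
    d = np.clip(d, 0, None)
    poly = u @ (np.sqrt(d * h2) * rng.standard_normal(n))
    return poly + rng.standard_normal(n) * np.sqrt(1 - h2)


def make_spec(y, sample_ids):
    return MixedModelSpec("t", list(sample_ids), y)


class TestFitNullReml:
    def test_optimum_beats_dense_grid(self):
        """REML at the optimizer's h2 >= every point of a 1000-point grid."""
        rng = np.random.default_rng(101)
        gm = random_gm(rng, 120, 300)
        grm = add_ridge(compute_grm(gm))
        y = simulate_trait(rng, grm, 0.4)
        spec = make_spec(y, gm.sample_ids)
        eig = eigendecompose(grm)
        vc = fit_null_reml(spec, eig)
        ystar = eig.u.T @ y
        xstar = eig.u.T @ spec.fixed_design()
        grid = np.linspace(1e-6, 1 - 1e-6, 1000)
        grid_ll = np.array([_reml_loglik(h, eig.d, ystar, xstar) for h in grid])
        assert vc.reml_loglik >= grid_ll.max() - 1e-6

    def test_h2_recovery_moderate_n(self):
        """ĥ² near the simulated value at n=400 (mean of 3 seeds)."""
        ests = []
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            gm = random_gm(rng, 400, 600)
            grm = add_ridge(compute_grm(gm))
            y = simulate_trait(rng, grm, 0.5)
            vc = fit_null_reml(make_spec(y, gm.sample_ids), grm)
            ests.append(vc.h2)
        assert abs(np.mean(ests) - 0.5) < 0.1

    def test_pure_noise_estimates_near_zero(self):
        """h2_true = 0: ĥ² <= 0.1 in at least 9 of 10 seeded replicates."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            gm = random_gm(rng, 500, 400)
            grm = add_ridge(compute_grm(gm))
            y = rng.standard_normal(500)
            vc = fit_null_reml(make_spec(y, gm.sample_ids), grm)
            hits += vc.h2 <= 0.1
        assert hits >= 9

    def test_input_validation(self):
        rng = np.random.default_rng(5)
        gm = random_gm(rng, 40, 50)
        grm = add_ridge(compute_grm(gm))
        with pytest.raises(ValueError, match="zero phenotypic variance"):
            fit_null_reml(make_spec(np.ones(40), gm.sample_ids), grm)
        small = GrmMatrix(gm.sample_ids[:10], grm.values[:10, :10])
        with pytest.raises(ValueError, match=">= 30"):
            fit_null_reml(make_spec(np.arange(10.0), gm.sample_ids[:10]), small)


class TestTestCnvr:
    def test_sigma_a_zero_collapses_to_ols(self):
        """With sigma2_a = 0 the Wald test equals OLS on the same design."""
        rng = np.random.default_rng(7)
        n = 200
        y = rng.standard_normal(n)
        w = rng.choice([-1.0, 0.0, 0.0, 1.0], size=n)
        grm = GrmMatrix([f"S{i}" for i in range(n)], np.eye(n))
        eig = eigendecompose(grm)
        spec = make_spec(y, grm.sample_ids)
        vc = VarianceComponents(0.0, 1.0, 0.0, 0.0)
        res = wald_test_cnvr(spec, vc, eig, w)
        ols = sm.OLS(y, sm.add_constant(w)).fit()
        assert res.beta == pytest.approx(ols.params[1], rel=1e-6)
        assert res.se == pytest.approx(ols.bse[1], rel=1e-6)
        assert res.p_value == pytest.approx(
            stats.chi2.sf(ols.tvalues[1] ** 2, 1), rel=1e-6)

    def test_matches_dense_explicit_inverse_gls(self):
        """n=20 system equals a direct solve with explicitly inverted V."""
        rng = np.random.default_rng(11)
        n, h2 = 20, 0.35
        a = rng.standard_normal((n, n))
        g = a @ a.T / n
        g *= n / np.trace(g)
        grm = GrmMatrix([f"S{i}" for i in range(n)], (g + g.T) / 2)
        y = rng.standard_normal(n)
        w = rng.choice([-1.0, 0.0, 1.0], size=n)
        spec = make_spec(y, grm.sample_ids)
        vc = VarianceComponents(h2 * 2.0, (1 - h2) * 2.0, h2, 0.0)
        res = wald_test_cnvr(spec, vc, eigendecompose(grm), w)
        # oracle: explicit inverse of the correlation-scale covariance
        sigma = h2 * grm.values + (1 - h2) * np.eye(n)
        si = np.linalg.inv(sigma)
        x = np.column_stack([np.ones(n), w])
        xtsx_inv = np.linalg.inv(x.T @ si @ x)
        beta = xtsx_inv @ x.T @ si @ y
        r = y - x @ beta
        s2 = (r @ si @ r) / (n - 2)
        se = np.sqrt(s2 * xtsx_inv[1, 1])
        assert res.beta == pytest.approx(beta[1], rel=1e-9)
        assert res.se == pytest.approx(se, rel=1e-9)
        assert res.wald_chi2 == pytest.approx((beta[1] / se) ** 2, rel=1e-9)

    def test_orthogonal_marker_has_zero_effect(self):
        rng = np.random.default_rng(13)
        n = 100
        y = rng.standard_normal(n)
        w = rng.standard_normal(n)
        yc = y - y.mean()
        w = w - w.mean()
        w -= (w @ yc) / (yc @ yc) * yc  # orthogonal to centered y
        grm = GrmMatrix([f"S{i}" for i in range(n)], np.eye(n))
        vc = VarianceComponents(0.0, 1.0, 0.0, 0.0)
        res = wald_test_cnvr(make_spec(y, grm.sample_ids), vc,
                        eigendecompose(grm), w)
        assert res.beta == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_constant_marker_degenerate(self):
        n = 50
        grm = GrmMatrix([f"S{i}" for i in range(n)], np.eye(n))
        vc = VarianceComponents(0.0, 1.0, 0.0, 0.0)
        res = wald_test_cnvr(make_spec(np.random.default_rng(0).standard_normal(n),
                                  grm.sample_ids),
                        vc, eigendecompose(grm), np.zeros(n))
        assert res.degenerate and res.p_value == 1.0

    def test_exact_refit_agrees_with_fast_path(self):
        """Per-marker REML refit within |Δlog10 p| <= 0.3 of the fast test."""
        rng = np.random.default_rng(17)
        gm = random_gm(rng, 300, 400)
        grm = add_ridge(compute_grm(gm))
        y = simulate_trait(rng, grm, 0.3)
        # add a real effect so the comparison covers small p too
        w0 = gm.codes[:, 0].astype(float)
        if w0.var() > 0:
            y = y + 0.8 * w0
        spec = make_spec(y, gm.sample_ids)
        eig = eigendecompose(grm)
        vc = fit_null_reml(spec, eig)
        for j in range(6):
            w = gm.codes[:, j].astype(float)
            if w.var() == 0:
                continue
            fast = wald_test_cnvr(spec, vc, eig, w)
            exact = wald_test_cnvr(spec, vc, eig, w, exact=True)
            assert abs(np.log10(fast.p_value) - np.log10(exact.p_value)) <= 0.3


class TestRunGwas:
    def test_identity_grm_matches_linear_model(self):
        """With G = I the mixed-model p equals the OLS t-test (chi2 vs t^2)."""
        rng = np.random.default_rng(19)
        n = 300
        gm = random_gm(rng, n, 50)
        grm = GrmMatrix(gm.sample_ids, np.eye(n))
        y = rng.standard_normal(n) + 0.4 * gm.codes[:, 0]
        phen = pd.DataFrame({"t": y}, index=pd.Index(gm.sample_ids,
                                                     name="sample_id"))
        run = run_gwas(gm, phen, "t", grm)
        for j, res in enumerate(run.results):
            if res.degenerate:
                continue
            ols = sm.OLS(y, sm.add_constant(gm.codes[:, j].astype(float))).fit()
            p_t = ols.pvalues[1]
            assert abs(np.log10(res.p_value) - np.log10(p_t)) <= 0.05

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(23)
        gm = random_gm(rng, 200, 40)
        grm = add_ridge(compute_grm(gm))
        y = simulate_trait(rng, grm, 0.3)
        idx = pd.Index(gm.sample_ids, name="sample_id")
        base = run_gwas(gm, pd.DataFrame({"t": y}, index=idx), "t", grm)
        shifted = run_gwas(gm, pd.DataFrame({"t": y + 100.0}, index=idx),
                           "t", grm)
        scaled = run_gwas(gm, pd.DataFrame({"t": 3.0 * y}, index=idx),
                          "t", grm)
        p0 = [r.p_value for r in base.results]
        assert p0 == pytest.approx([r.p_value for r in shifted.results],
                                   rel=1e-6)
        assert p0 == pytest.approx([r.p_value for r in scaled.results],
                                   rel=1e-6)
        for r0, rs in zip(base.results, scaled.results):
            if not r0.degenerate:
                assert rs.beta == pytest.approx(3.0 * r0.beta, rel=1e-6)

    def test_permuting_y_breaks_association(self):
        rng = np.random.default_rng(29)
        gm = random_gm(rng, 300, 200)
        grm = add_ridge(compute_grm(gm))
        w = gm.codes[:, 5].astype(float)
        y = simulate_trait(rng, grm, 0.2) + 1.5 * w
        idx = pd.Index(gm.sample_ids, name="sample_id")
        perm = rng.permutation(300)
        run = run_gwas(gm, pd.DataFrame({"t": y[perm]}, index=idx), "t", grm)
        pvals = [r.p_value for r in run.results if not r.degenerate]
        assert abs(np.median(pvals) - 0.5) <= 0.1
        assert run.results[5].p_value > significance_threshold(len(pvals))

    def test_missing_phenotypes_dropped_listwise(self):
        rng = np.random.default_rng(31)
        gm = random_gm(rng, 60, 30)
        grm = add_ridge(compute_grm(gm))
        y = rng.standard_normal(60)
        y[:10] = np.nan
        idx = pd.Index(gm.sample_ids, name="sample_id")
        run = run_gwas(gm, pd.DataFrame({"t": y}, index=idx), "t", grm)
        assert run.n_used == 50

    def test_error_cases(self):
        rng = np.random.default_rng(37)
        gm = random_gm(rng, 40, 10)
        grm = add_ridge(compute_grm(gm))
        idx = pd.Index(gm.sample_ids, name="sample_id")
        phen = pd.DataFrame({"t": [np.nan] * 40}, index=idx)
        with pytest.raises(ValueError, match="non-missing"):
            run_gwas(gm, phen, "t", grm)
        with pytest.raises(ValueError, match="not in phenotype"):
            run_gwas(gm, phen, "absent", grm)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(41)
        gm = random_gm(rng, 100, 60)
        grm = add_ridge(compute_grm(gm))
        y = simulate_trait(rng, grm, 0.3)
        idx = pd.Index(gm.sample_ids, name="sample_id")
        phen = pd.DataFrame({"t": y}, index=idx)
        a = run_gwas(gm, phen, "t", grm)
        b = run_gwas(gm, phen, "t", grm)
        assert [r.p_value for r in a.results] == [r.p_value for r in b.results]


class TestThresholds:
    def test_bonferroni_arithmetic(self):
        assert significance_threshold(11_035, 0.05) == 0.05 / 11_035
        assert significance_threshold(11_035, 0.05) == pytest.approx(
            4.5310e-6, rel=1e-4)
        assert significance_threshold(1) == 0.05
        with pytest.raises(ValueError):
            significance_threshold(0)

    def test_bh_textbook_example(self):
        q = bh_qvalues(np.array([0.001, 0.02, 0.9]))
        assert q == pytest.approx([0.003, 0.03, 0.9])


class TestManhattanQq:
    def _results(self, pvals, cnvrs):
        out = []
        for (p, c) in zip(pvals, cnvrs):
            chi2 = float(stats.chi2.isf(p, 1))
            out.append(AssociationResult(c.cnvr_id, 0.1, 0.1, chi2, p,
                                         n_used=100))
        return out

    def _cnvrs(self, n, chroms=("1",)):
        out = []
        for i in range(n):
            chrom = chroms[i % len(chroms)]
            start = 1000 + 500 * i
            out.append(Cnvr(f"R{i:05d}", chrom, start, start + 99,
                            CnvrType.LOSS))
        return out

    def test_uniform_p_gives_lambda_near_one(self):
        rng = np.random.default_rng(43)
        m = 2000
        cnvrs = self._cnvrs(m)
        pvals = rng.uniform(size=m)
        _, qq, lam = manhattan_qq_data(self._results(pvals, cnvrs), cnvrs)
        assert abs(lam - 1.0) <= 0.1
        assert len(qq) == m

    def test_single_p_of_001(self):
        cnvrs = self._cnvrs(1)
        mh, _, _ = manhattan_qq_data(self._results([0.01], cnvrs), cnvrs)
        assert mh.loc[0, "minus_log10_p"] == pytest.approx(2.0)

    def test_cumulative_offsets_increase_across_chromosomes(self):
        cnvrs = self._cnvrs(30, chroms=("1", "2", "3"))
        rng = np.random.default_rng(47)
        mh, _, _ = manhattan_qq_data(
            self._results(rng.uniform(size=30), cnvrs), cnvrs)
        by_chrom = mh.groupby("chrom", sort=False)["cum_pos"]
        maxes = by_chrom.max().to_numpy()
        mins = by_chrom.min().to_numpy()
        assert all(mins[k + 1] > maxes[k] for k in range(2))

    def test_unknown_result_id_rejected(self):
        cnvrs = self._cnvrs(1)
        res = self._results([0.5], cnvrs)
        res[0].cnvr_id = "ghost"
        with pytest.raises(ValueError, match="ghost"):
            manhattan_qq_data(res, cnvrs)
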