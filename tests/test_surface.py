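"""Surface models: tricube LOESS, Lorentzian evaluation/fit, regression inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prandikit import (
    Diet,
    LoessConfig,
    LorentzianParams,
    Sex,
    SurfacePoint,
    aggregate_daily_means,
    anova_from_sums,
    compute_inference,
    fit_lorentzian,
    loess_fit_predict,
    lorentzian_eval,
    tricube_weight,
)
from prandikit.surface import FitError, LoessError, lorentzian_jacobian
from prandikit.simulate import TRUE_PARAMS

SUGAR = TRUE_PARAMS[Diet.SUGAR_LIQUID]
PROTEIN = TRUE_PARAMS[Diet.PROTEIN_LIQUID]


def _grid_points(params: LorentzianParams, n_side: int = 60) -> list[SurfacePoint]:
    """Noise-free observations of the surface along an (age, intake) lattice."""
    rng = np.random.default_rng(12)
    x = np.linspace(1, 60, n_side)
    y = params.y0 + params.gamma * rng.uniform(-2, 2, n_side)
    return [SurfacePoint(a, b, lorentzian_eval(params, a, b)) for a, b in zip(x, y)]


class TestTricube:
    @pytest.mark.parametrize("u,w", [(0.0, 1.0), (1.0, 0.0), (0.5, 0.669921875), (-0.5, 0.669921875), (2.0, 0.0)])
    def test_values(self, u, w):
        assert tricube_weight(u) == pytest.approx(w)

    @given(u=st.floats(-2, 2, allow_nan=False))
    @settings(max_examples=200, derandomize=True)
    def test_even_bounded(self, u):
        w = tricube_weight(u)
        assert 0 <= w <= 1
        assert w == pytest.approx(tricube_weight(-u))

    @given(a=st.floats(0, 1, exclude_max=True), b=st.floats(0, 1, exclude_max=True))
    @settings(max_examples=200, derandomize=True)
    def test_non_increasing_on_unit_interval(self, a, b):
        lo, hi = sorted([a, b])
        assert tricube_weight(lo) >= tricube_weight(hi)


class TestLorentzianEval:
    def test_peak_equals_amplitude(self):
        assert lorentzian_eval(SUGAR, 32.0000, 0.6276) == pytest.approx(24.0087)
        assert lorentzian_eval(PROTEIN, 28.3359, 0.1258) == pytest.approx(14.8297)

    def test_half_width_halves_the_peak(self):
        for p in (SUGAR, PROTEIN):
            assert lorentzian_eval(p, p.x0 + p.beta, p.y0) == pytest.approx(p.alpha / 2)
            assert lorentzian_eval(p, p.x0 - p.beta, p.y0) == pytest.approx(p.alpha / 2)
            assert lorentzian_eval(p, p.x0, p.y0 + p.gamma) == pytest.approx(p.alpha / 2)
            assert lorentzian_eval(p, p.x0, p.y0 - p.gamma) == pytest.approx(p.alpha / 2)

    def test_off_peak_closed_form(self):
        # independent evaluation of alpha / ((1+u^2)(1+v^2)) at (40, 0.5)
        u = (40 - SUGAR.x0) / SUGAR.beta
        v = (0.5 - SUGAR.y0) / SUGAR.gamma
        expected = SUGAR.alpha / ((1 + u * u) * (1 + v * v))
        assert lorentzian_eval(SUGAR, 40, 0.5) == pytest.approx(expected)
        assert expected == pytest.approx(11.29, abs=0.005)

    @given(d=st.floats(0, 50), y=st.floats(0, 2))
    @settings(max_examples=100, derandomize=True)
    def test_symmetry_about_peak(self, d, y):
        assert lorentzian_eval(SUGAR, SUGAR.x0 + d, y) == pytest.approx(
            lorentzian_eval(SUGAR, SUGAR.x0 - d, y)
        )

    def test_jacobian_matches_finite_differences(self):
        x = np.array([10.0, 32.0, 50.0])
        y = np.array([0.3, 0.63, 0.9])
        J = lorentzian_jacobian(SUGAR, x, y)
        eps = 1e-7
        base = np.array([SUGAR.x0, SUGAR.y0, SUGAR.alpha, SUGAR.beta, SUGAR.gamma])
        for j in range(5):
            bumped = base.copy()
            bumped[j] += eps
            p2 = LorentzianParams(*bumped)
            fd = (lorentzian_eval(p2, x, y) - lorentzian_eval(SUGAR, x, y)) / eps
            assert np.allclose(J[:, j], fd, rtol=1e-4, atol=1e-6)


class TestLoess:
    @staticmethod
    def _plane_points(n=50, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, n)
        y = rng.uniform(0, 5, n)
        return [SurfacePoint(a, b, 2 * a + 3 * b + 1) for a, b in zip(x, y)]

    @pytest.mark.parametrize("q", [0.2, 0.5, 0.999])
    def test_degree_one_exactness_on_plane(self, q):
        pts = self._plane_points()
        queries = [(5.0, 2.5), (2.0, 4.0), (7.7, 1.3)]
        preds = loess_fit_predict(pts, LoessConfig(q=q), queries)
        expected = [2 * a + 3 * b + 1 for a, b in queries]
        assert np.allclose(preds, expected, rtol=1e-9, atol=1e-9)

    def test_uniform_weights_full_span_equals_global_ols(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 40)
        y = rng.uniform(0, 5, 40)
        z = 2 * x + 3 * y + 1 + rng.normal(0, 1, 40)
        pts = [SurfacePoint(*t) for t in zip(x, y, z)]
        pred = loess_fit_predict(pts, LoessConfig(q=0.999, weights="uniform"), [(5.0, 2.5)])
        A = np.column_stack([np.ones(40), x, y])
        coef = np.linalg.lstsq(A, z, rcond=None)[0]
        assert pred[0] == pytest.approx(coef @ [1, 5.0, 2.5])

    def test_constant_response(self):
        rng = np.random.default_rng(1)
        pts = [SurfacePoint(a, b, 7.5) for a, b in zip(rng.uniform(0, 9, 30), rng.uniform(0, 9, 30))]
        preds = loess_fit_predict(pts, LoessConfig(q=0.4), [(4.0, 4.0), (1.0, 8.0)])
        assert np.allclose(preds, 7.5)

    def test_collinear_neighborhood_raises(self):
        pts = [SurfacePoint(float(i), 2.0, float(i)) for i in range(20)]  # y constant
        with pytest.raises(LoessError):
            loess_fit_predict(pts, LoessConfig(q=0.5), [(5.0, 2.0)])

    def test_inadmissible_q_rejected(self):
        pts = self._plane_points(n=10)
        with pytest.raises(ValueError):
            loess_fit_predict(pts, LoessConfig(q=1.5), [(1.0, 1.0)])
        with pytest.raises(ValueError):
            loess_fit_predict(pts, LoessConfig(q=0.1), [(1.0, 1.0)])  # q <= (λ+1)/n


class TestAggregateDailyMeans:
    def test_arithmetic_means_per_day(self, tiny_cohort):
        pts = aggregate_daily_means(tiny_cohort)
        # day 3: corrected intakes (1, 0), eggs (8, 2)
        by_x = {p.x: p for p in pts}
        assert by_x[3.0].y == pytest.approx(0.5)
        assert by_x[3.0].z == pytest.approx(5.0)
        assert len(pts) == 3

    def test_length_bounded_by_last_death(self, tiny_cohort):
        pts = aggregate_daily_means(tiny_cohort, max_age=60)
        assert len(pts) == max(tiny_cohort.death_day.values())

    def test_requires_egg_data(self, default_study):
        males = default_study.cohort(Sex.M, Diet.SUGAR_LIQUID)
        with pytest.raises(ValueError, match="female"):
            aggregate_daily_means(males)

    def test_noiseless_cohort_lies_on_surface(self, noiseless_study):
        """Without noise the aggregated z equal the generating surface exactly."""
        table = noiseless_study.cohort(Sex.F, Diet.PROTEIN_LIQUID)
        pts = aggregate_daily_means(table, max_age=60)
        p = noiseless_study.true_params[Diet.PROTEIN_LIQUID]
        for pt in pts:
            assert pt.z == pytest.approx(lorentzian_eval(p, pt.x, pt.y), rel=1e-12)


class TestFitLorentzian:
    def test_exact_recovery_from_noise_free_grid(self):
        """60 noise-free points from the protein parameters: full recovery, r2 = 1."""
        pts = _grid_points(PROTEIN)
        params, inf = fit_lorentzian(pts)
        assert np.allclose(params.as_array(), PROTEIN.as_array(), rtol=1e-4)
        assert inf.r2 == pytest.approx(1.0, abs=1e-10)

    def test_invariant_to_point_order(self):
        pts = _grid_points(SUGAR)
        p1, _ = fit_lorentzian(pts)
        p2, _ = fit_lorentzian(list(reversed(pts)))
        assert np.allclose(p1.as_array(), p2.as_array(), rtol=1e-8)

    def test_z_rescaling_scales_amplitude_only(self):
        pts = _grid_points(SUGAR)
        scaled = [SurfacePoint(p.x, p.y, 3.5 * p.z) for p in pts]
        p1, _ = fit_lorentzian(pts)
        p2, _ = fit_lorentzian(scaled)
        assert p2.alpha == pytest.approx(3.5 * p1.alpha, rel=1e-6)
        for name in ("x0", "y0", "beta", "gamma"):
            assert getattr(p2, name) == pytest.approx(getattr(p1, name), rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_lorentzian(_grid_points(SUGAR)[:5])

    def test_constant_response_rejected(self):
        pts = [SurfacePoint(float(i), 0.5, 4.0) for i in range(1, 21)]
        with pytest.raises(FitError, match="constant"):
            fit_lorentzian(pts)

    def test_recovery_bias_shrinks_with_noise(self):
        """Parameter bias goes to zero as observation noise goes to zero."""
        rng = np.random.default_rng(5)
        base = _grid_points(PROTEIN)
        errs = []
        for sd in (0.5, 0.05, 0.005):
            noisy = [SurfacePoint(p.x, p.y, p.z + rng.normal(0, sd)) for p in base]
            params, _ = fit_lorentzian(noisy)
            errs.append(np.abs(params.as_array() / PROTEIN.as_array() - 1).max())
        assert errs[0] > errs[2]
        assert errs[2] < 1e-2


class TestInference:
    def test_printed_anova_arithmetic(self):
        """F, R2, adjusted R2 and SE of estimate follow from the SS table."""
        sugar = anova_from_sums(ss_res=772.8826, n=60, ss_reg=742.2742)
        assert sugar["F"] == pytest.approx(13.2055, abs=5e-4)
        assert sugar["ms_reg"] == pytest.approx(185.5686, abs=5e-4)
        assert sugar["r2"] == pytest.approx(0.4899, abs=5e-4)
        assert sugar["adj_r2"] == pytest.approx(0.4528, abs=5e-4)
        assert sugar["se_estimate"] == pytest.approx(3.7487, abs=5e-4)
        assert sugar["r"] == pytest.approx(0.6999, abs=5e-4)
        protein = anova_from_sums(ss_res=134.1736, n=60, ss_reg=1262.7094)
        assert protein["F"] == pytest.approx(129.4014, abs=5e-4)
        assert protein["r2"] == pytest.approx(0.9039, abs=5e-4)
        assert protein["adj_r2"] == pytest.approx(0.8970, abs=5e-4)
        assert protein["se_estimate"] == pytest.approx(1.5619, abs=5e-4)

    def test_t_is_estimate_over_se(self):
        assert 9.2432 / 1.7346 == pytest.approx(5.3288, abs=5e-4)  # sugar beta
        assert 28.3359 / 0.6892 == pytest.approx(41.1140, abs=5e-3)  # protein x0

    def test_identities_hold_on_a_real_fit(self, default_study):
        table = default_study.cohort(Sex.F, Diet.PROTEIN_LIQUID)
        pts = aggregate_daily_means(table, max_age=60)
        params, inf = fit_lorentzian(pts)
        assert inf.ss_total == pytest.approx(inf.ss_reg + inf.ss_res)
        assert inf.r2 == pytest.approx(inf.ss_reg / inf.ss_total)
        assert inf.se_estimate**2 == pytest.approx(inf.ms_res)
        assert inf.adj_r2 == pytest.approx(1 - inf.ms_res * inf.df_total / inf.ss_total)
        assert inf.df_reg == 4 and inf.df_res == len(pts) - 5 and inf.df_total == len(pts) - 1
        for name in ("x0", "y0", "alpha", "beta", "gamma"):
            assert inf.t[name] == pytest.approx(getattr(params, name) / inf.se[name])
            assert 0 <= inf.p[name] <= 1

    def test_perfect_fit_scalars(self):
        pts = _grid_points(PROTEIN)
        inf = compute_inference(pts, PROTEIN)
        assert inf.r2 == pytest.approx(1.0)
        assert inf.se_estimate == pytest.approx(0.0, abs=1e-12)

    def test_simulated_protein_fit_is_strong(self, default_study):
        """Default protein cohort: high R2 and a large, significant F."""
        table = default_study.cohort(Sex.F, Diet.PROTEIN_LIQUID)
        pts = aggregate_daily_means(table, max_age=60)
        _, inf = fit_lorentzian(pts)
        assert inf.r2 > 0.7
        assert inf.F > 20
        assert inf.F_p < 1e-6
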