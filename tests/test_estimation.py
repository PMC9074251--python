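"""Non-iterative K-value parameter estimation: tie-line geometry, one-shot
phase-equation residuals, and the multistart fit."""

import numpy as np
import pytest

from llextract import (
    FitConfig,
    TieLine,
    TieLineDataset,
    estimate_nrtl,
    feed_on_tieline,
    generate_tielines,
    kvalue_residual,
    lever_fraction,
    lle_flash,
)
from llextract.estimation import _midpoint_z1

T = 298.15


def _random_tieline(rng):
    x_aq = rng.dirichlet([8, 1, 0.2])
    x_org = rng.dirichlet([0.5, 2, 6])
    return TieLine(x_org=x_org, x_aq=x_aq, T=T)


class TestFeedOnTieline:
    def test_endpoint_and_midpoint(self, broth_system):
        rng = np.random.default_rng(1)
        tl = _random_tieline(rng)
        near = tl.x_aq[0] - 1e-9 * np.sign(tl.x_aq[0] - tl.x_org[0])
        z = feed_on_tieline(tl, near)
        np.testing.assert_allclose(z, tl.x_aq, atol=1e-7)
        mid = feed_on_tieline(tl, 0.5 * (tl.x_aq[0] + tl.x_org[0]))
        np.testing.assert_allclose(mid, 0.5 * (tl.x_aq + tl.x_org), atol=1e-12)

    def test_matches_linear_system_oracle(self):
        """Collinearity + closure solved independently as a linear system."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            tl = _random_tieline(rng)
            lo, hi = sorted((tl.x_aq[0], tl.x_org[0]))
            z1 = rng.uniform(lo + 1e-6, hi - 1e-6)
            z = feed_on_tieline(tl, z1)
            # oracle: unknowns (z2, z3, t); equations z = x_org + t d
            d = tl.x_aq - tl.x_org
            A = np.array(
                [
                    [0.0, 0.0, d[0]],
                    [-1.0, 0.0, d[1]],
                    [0.0, -1.0, d[2]],
                ]
            )
            b = np.array([z1 - tl.x_org[0], -tl.x_org[1], -tl.x_org[2]])
            z2, z3, t = np.linalg.solve(A, b)
            np.testing.assert_allclose(z, [z1, z2, z3], atol=1e-12)
            assert z.sum() == pytest.approx(1.0, abs=1e-12)  # closure
            assert np.all(z >= 0) and np.all(z <= 1)

    def test_outside_interval_raises(self):
        tl = _random_tieline(np.random.default_rng(3))
        hi = max(tl.x_aq[0], tl.x_org[0])
        with pytest.raises(ValueError, match="strictly between"):
            feed_on_tieline(tl, hi + 0.01)


class TestLeverFraction:
    def test_endpoints_and_midpoint(self):
        tl = _random_tieline(np.random.default_rng(5))
        assert lever_fraction(tl, tl.x_aq) == pytest.approx(0.0, abs=1e-12)
        assert lever_fraction(tl, tl.midpoint()) == pytest.approx(0.5, abs=1e-12)

    def test_matches_collinearity_parameter(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            tl = _random_tieline(rng)
            t = rng.uniform(0.05, 0.95)
            z = tl.x_aq + t * (tl.x_org - tl.x_aq)
            L = lever_fraction(tl, z)
            assert L == pytest.approx(t, abs=1e-10)
            np.testing.assert_allclose(
                (1 - L) * tl.x_aq + L * tl.x_org, z, atol=1e-10
            )

    def test_noncollinear_raises(self):
        tl = _random_tieline(np.random.default_rng(13))
        z = tl.midpoint() + np.array([0.05, -0.02, -0.03])
        with pytest.raises(ValueError, match="collinearity residual"):
            lever_fraction(tl, z)


class TestKvalueResidual:
    def test_zero_at_exactly_reproduced_tieline(self, broth_system):
        """Params whose flash reproduces the tie-line give zero residual:
        the non-iterative shortcut agrees with the converged flash."""
        _, params = broth_system
        fr = lle_flash([0.75, 0.05, 0.20], T, params)
        tl = fr.tieline()
        _, resid = kvalue_residual(params, tl)
        assert np.max(np.abs(resid)) < 1e-8

    def test_ideal_params_collapse_to_feed(self, ideal_ternary, broth_system):
        """tau = 0 forces K = 1, so both computed phases equal the feed and
        the residual is the measured phase difference from it."""
        _, ideal = ideal_ternary
        _, params = broth_system
        tl = lle_flash([0.75, 0.05, 0.20], T, params).tieline()
        computed, resid = kvalue_residual(ideal, tl)
        z = feed_on_tieline(tl, _midpoint_z1(tl))
        np.testing.assert_allclose(computed.x_aq, z, atol=1e-12)
        np.testing.assert_allclose(computed.x_org, z, atol=1e-12)
        np.testing.assert_allclose(
            resid, np.concatenate([z - tl.x_aq, z - tl.x_org]), atol=1e-12
        )

    def test_fixture_roundtrip(self, broth_system):
        """Ground-truth params on ground-truth (noiseless) tie-lines."""
        res = generate_tielines(broth_system, n=5, noise_sd=0.0, seed=0)
        for tl in res.truth.tielines:
            _, resid = kvalue_residual(broth_system[1], tl)
            assert np.max(np.abs(resid)) < 1e-6


class TestEstimate:
    def test_noiseless_truth_is_global_minimum(self, broth_system):
        res = generate_tielines(broth_system, n=4, noise_sd=0.0, seed=0)
        fit = estimate_nrtl(
            res.data, FitConfig(n_starts=2, seed=1, initial=broth_system[1])
        )
        assert fit.objective < 1e-8
        assert all(fit.gibbs_feasible)

    def test_objective_invariant_to_ordering_and_phase_swap(self, broth_system):
        res = generate_tielines(broth_system, n=4, noise_sd=0.002, seed=3)
        data = res.data
        swapped = TieLineDataset(
            data.components,
            tuple(
                TieLine(x_org=tl.x_aq, x_aq=tl.x_org, T=tl.T)  # stored swapped
                for tl in reversed(data.tielines)
            ),
            T=data.T,
            noise_sd=data.noise_sd,
        )
        p = broth_system[1]
        r1 = np.sqrt(
            np.mean([kvalue_residual(p, tl)[1] ** 2 for tl in data.tielines])
        )
        r2 = np.sqrt(
            np.mean([kvalue_residual(p, tl)[1] ** 2 for tl in swapped.tielines])
        )
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_parameter_recovery_from_noisy_data(self, broth_system):
        """Core regression: 6 tie-lines at 0.003 noise; the fitted model must
        reproduce the noiseless binodal within RMS 0.01 mole fraction."""
        res = generate_tielines(broth_system, n=6, noise_sd=0.003, seed=7)
        fit = estimate_nrtl(res.data, FitConfig(n_starts=16, seed=42))
        assert all(fit.gibbs_feasible)
        errs = []
        for tl in res.truth.tielines:
            z = feed_on_tieline(tl, _midpoint_z1(tl))
            fr = lle_flash(z, T, fit.params)
            errs.extend(fr.x_I - tl.x_aq)
            errs.extend(fr.x_II - tl.x_org)
        rms = float(np.sqrt(np.mean(np.square(errs))))
        assert rms < 0.01

    def test_identifiability_in_tieline_space(self, broth_system):
        """Fits reached from different seeds may differ in raw parameters but
        must agree in predicted tie-lines when objectives are this close."""
        res = generate_tielines(broth_system, n=6, noise_sd=0.0, seed=0)
        fit_a = estimate_nrtl(
            res.data, FitConfig(n_starts=2, seed=1, initial=broth_system[1])
        )
        fit_b = estimate_nrtl(res.data, FitConfig(n_starts=10, seed=99))
        if abs(fit_a.objective - fit_b.objective) < 1e-6:
            for tl in res.truth.tielines:
                z = feed_on_tieline(tl, _midpoint_z1(tl))
                fa = lle_flash(z, T, fit_a.params)
                fb = lle_flash(z, T, fit_b.params)
                assert np.max(np.abs(fa.x_I - fb.x_I)) < 1e-3
                assert np.max(np.abs(fa.x_II - fb.x_II)) < 1e-3

    def test_too_few_tielines_raises(self, broth_system):
        res = generate_tielines(broth_system, n=2, noise_sd=0.0, seed=0)
        one = TieLineDataset(res.data.components, res.data.tielines[:1], T=T)
        with pytest.raises(ValueError, match="at least 2"):
            estimate_nrtl(one)

    def test_predicted_tielines_export(self, broth_system):
        res = generate_tielines(broth_system, n=4, noise_sd=0.0, seed=0)
        fit = estimate_nrtl(
            res.data, FitConfig(n_starts=1, seed=1, initial=broth_system[1])
        )
        pred = fit.predicted_tielines(res.data)
        assert len(pred) == 4
        for p, tl in zip(pred, res.truth.tielines):
            assert np.max(np.abs(p.x_aq - tl.x_aq)) < 1e-6
            assert np.max(np.abs(p.x_org - tl.x_org)) < 1e-6
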