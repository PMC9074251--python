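"""NRTL activity coefficients, excess/mixing Gibbs energy, and stability."""

import numpy as np
import pytest

from llextract import (
    ComponentSet,
    NrtlParameterSet,
    PhaseSplit,
    activity_coefficients,
    excess_gibbs_reduced,
    gibbs_mixing_reduced,
    stability_test,
)
from llextract.nrtl import ln_activity_coefficients

from conftest import gibbs_of_split

T = 298.15


def _random_params(rng, n):
    tau = rng.uniform(-2, 4, size=(n, n))
    np.fill_diagonal(tau, 0.0)
    alpha = np.full((n, n), rng.uniform(0.2, 0.47))
    np.fill_diagonal(alpha, 0.0)
    comps = ComponentSet(tuple(f"c{i}" for i in range(n)))
    return NrtlParameterSet(comps, tau, alpha)


def _random_x(rng, n):
    x = rng.dirichlet(np.ones(n) * 2.0)
    return np.clip(x, 1e-4, None) / np.clip(x, 1e-4, None).sum()


class TestActivityCoefficients:
    def test_pure_component_limit(self, broth_system):
        _, params = broth_system
        g = activity_coefficients([1.0, 0.0, 0.0], T, params)
        assert g[0] == pytest.approx(1.0, abs=1e-12)

    def test_ideal_mixture(self, ideal_ternary):
        _, params = ideal_ternary
        g = activity_coefficients([0.2, 0.3, 0.5], T, params)
        np.testing.assert_allclose(g, 1.0, atol=1e-14)

    def test_binary_closed_form(self):
        # two-component NRTL closed form, evaluated by hand:
        # ln g1 = x2^2 [tau21 (G21/(x1+x2 G21))^2 + tau12 G12/(x2+x1 G12)^2]
        comps = ComponentSet(("a", "b"))
        tau = np.array([[0.0, 1.0], [1.0, 0.0]])
        alpha = np.array([[0.0, 0.3], [0.3, 0.0]])
        params = NrtlParameterSet(comps, tau, alpha)
        G = np.exp(-0.3 * 1.0)
        x1 = x2 = 0.5
        ln_g1 = x2**2 * (1.0 * (G / (x1 + x2 * G)) ** 2 + 1.0 * G / (x2 + x1 * G) ** 2)
        g = activity_coefficients([0.5, 0.5], T, params)
        assert g[0] == pytest.approx(np.exp(ln_g1), rel=1e-12)
        assert g[1] == pytest.approx(np.exp(ln_g1), rel=1e-12)  # symmetric

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_gamma_is_derivative_of_excess_gibbs(self, n):
        """ln gamma_i must equal d(n G^E/RT)/dn_i (central differences)."""
        rng = np.random.default_rng(n)
        for _ in range(5):
            params = _random_params(rng, n)
            x = _random_x(rng, n)
            ln_g = ln_activity_coefficients(x, T, params)
            h = 1e-6
            for i in range(n):
                # perturb mole numbers: n_tot = 1, dn_i = +/- h
                def nGE(dn):
                    ni = x.copy()
                    ni[i] += dn
                    tot = ni.sum()
                    return tot * excess_gibbs_reduced(ni / tot, T, params)

                fd = (nGE(h) - nGE(-h)) / (2 * h)
                assert fd == pytest.approx(ln_g[i], abs=1e-7)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_gibbs_duhem(self, n):
        """sum_i x_i dlngamma_i/dx_j = 0 along any simplex direction."""
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            params = _random_params(rng, n)
            x = _random_x(rng, n)
            h = 1e-6
            for j in range(n - 1):
                d = np.zeros(n)
                d[j], d[-1] = 1.0, -1.0  # stay on the simplex
                lg_p = ln_activity_coefficients(x + h * d, T, params)
                lg_m = ln_activity_coefficients(x - h * d, T, params)
                gd = float(x @ (lg_p - lg_m) / (2 * h))
                assert abs(gd) < 1e-6

    def test_permutation_symmetry(self, broth_system):
        _, params = broth_system
        x = np.array([0.6, 0.1, 0.3])
        perm = [2, 0, 1]
        comps_p = ComponentSet(tuple(params.components.names[i] for i in perm))
        params_p = NrtlParameterSet(
            comps_p, params.tau[np.ix_(perm, perm)], params.alpha[np.ix_(perm, perm)]
        )
        g = activity_coefficients(x, T, params)
        g_p = activity_coefficients(x[perm], T, params_p)
        np.testing.assert_allclose(g_p, g[perm], rtol=1e-12)

    def test_dimension_mismatch_raises(self, broth_system):
        _, params = broth_system
        with pytest.raises(ValueError, match="entries"):
            activity_coefficients([0.5, 0.5], T, params)

    def test_negative_composition_raises(self, broth_system):
        _, params = broth_system
        with pytest.raises(ValueError, match="negative"):
            activity_coefficients([1.1, -0.1, 0.0], T, params)

    def test_temperature_dependent_tau(self):
        comps = ComponentSet(("a", "b"))
        a = np.array([[0.0, 1.0], [0.5, 0.0]])
        b = np.array([[0.0, 300.0], [100.0, 0.0]])
        alpha = np.array([[0.0, 0.2], [0.2, 0.0]])
        params = NrtlParameterSet(
            comps, a + b / 298.15, alpha, T_ref=298.15, tau_a=a, tau_b=b
        )
        np.testing.assert_allclose(params.tau_at(298.15), a + b / 298.15)
        np.testing.assert_allclose(params.tau_at(350.0), a + b / 350.0)


class TestGibbsMixing:
    def test_ideal_entropy_of_mixing(self):
        comps = ComponentSet(("a", "b"))
        params = NrtlParameterSet(
            comps, np.zeros((2, 2)), np.array([[0.0, 0.3], [0.3, 0.0]])
        )
        split = PhaseSplit.single([0.5, 0.5], T)
        assert gibbs_mixing_reduced(split, params) == pytest.approx(np.log(0.5))

    def test_identical_phases_equal_single(self, broth_system):
        _, params = broth_system
        x = np.array([0.5, 0.2, 0.3])
        one = PhaseSplit.single(x, T)
        two = PhaseSplit(phases=((x, 0.5), (x, 0.5)), T=T)
        assert gibbs_mixing_reduced(two, params) == pytest.approx(
            gibbs_mixing_reduced(one, params), abs=1e-14
        )

    def test_zero_composition_convention(self, broth_system):
        _, params = broth_system
        split = PhaseSplit.single([0.7, 0.0, 0.3], T)
        assert np.isfinite(gibbs_mixing_reduced(split, params))

    def test_demixing_split_below_feed_grid_oracle(self, binary_demix):
        """Equilibrium two-phase split beats the homogeneous feed, verified
        by a 1-D brute-force scan over all binary splits."""
        _, params = binary_demix
        z = np.array([0.5, 0.5])
        g_feed = gibbs_of_split([z], [1.0], T, params)
        best = g_feed
        for x1a in np.linspace(0.005, 0.495, 200):
            for x1b in np.linspace(0.505, 0.995, 200):
                # lever rule fixes the split fractions
                l_b = (z[0] - x1a) / (x1b - x1a)
                if not 0 < l_b < 1:
                    continue
                g = gibbs_of_split(
                    [np.array([x1a, 1 - x1a]), np.array([x1b, 1 - x1b])],
                    [1 - l_b, l_b],
                    T,
                    params,
                )
                best = min(best, g)
        assert best < g_feed - 1e-3  # grid finds a strictly better split
        from llextract import lle_flash

        fr = lle_flash(z, T, params)
        g_eq = gibbs_of_split([fr.x_I, fr.x_II], [1 - fr.L_II, fr.L_II], T, params)
        assert g_eq <= best + 1e-6  # equilibrium at least as good as the grid


class TestStability:
    def test_ideal_always_stable(self, ideal_ternary):
        _, params = ideal_ternary
        assert stability_test([0.3, 0.3, 0.4], T, params).stable

    def test_demixing_binary_unstable(self, binary_demix):
        _, params = binary_demix
        res = stability_test([0.5, 0.5], T, params)
        assert not res.stable
        assert res.tpd < -1e-8
        assert res.trial is not None

    def test_vertex_stable(self, broth_system):
        _, params = broth_system
        assert stability_test([0.0, 0.0, 1.0], T, params).stable


class TestParameterSet:
    def test_invariant_violations_raise(self):
        comps = ComponentSet(("a", "b"))
        with pytest.raises(ValueError, match="diagonal"):
            NrtlParameterSet(comps, np.eye(2), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="symmetric"):
            NrtlParameterSet(
                comps, np.zeros((2, 2)), np.array([[0.0, 0.2], [0.3, 0.0]])
            )
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            NrtlParameterSet(
                comps, np.zeros((2, 2)), np.array([[0.0, 1.2], [1.2, 0.0]])
            )

    def test_pair_dict_roundtrip(self, broth_system):
        _, params = broth_system
        back = NrtlParameterSet.from_dict(params.to_dict())
        np.testing.assert_allclose(back.tau, params.tau)
        np.testing.assert_allclose(back.alpha, params.alpha)
        assert back.components.names == params.components.names

    def test_missing_pairs_default_ideal(self, caplog):
        d = {
            "components": ["a", "b", "c"],
            "T_ref_K": 298.15,
            "pairs": [{"i": "a", "j": "b", "tau_ij": 1.0, "tau_ji": 2.0, "alpha": 0.2}],
        }
        import logging

        with caplog.at_level(logging.WARNING):
            p = NrtlParameterSet.from_dict(d)
        assert "defaulting to ideal" in caplog.text
        assert p.tau[0, 2] == 0.0 and p.alpha[0, 2] == 0.3
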