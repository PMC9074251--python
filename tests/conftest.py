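"""Shared fixtures and independent oracles.

The flash oracle here finds the equilibrium split by direct minimization of
the Gibbs energy of mixing over the phase-II mole numbers with a
general-purpose bounded optimizer — a route entirely separate from the
successive-substitution flash it cross-checks.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from llextract import (
    ComponentSet,
    NrtlParameterSet,
    make_demixing_system,
)
from llextract.nrtl import ln_activity_coefficients, _xlnx


# --------------------------------------------------------------------------
# oracles


def gibbs_of_split(x_list, l_list, T, params) -> float:
    """Brute-force dG_mix/RT of an arbitrary split (no PhaseSplit machinery)."""
    total = 0.0
    for x, l in zip(x_list, l_list):
        x = np.asarray(x, float)
        if l == 0:
            continue
        ln_g = ln_activity_coefficients(x, T, params)
        total += l * float(np.sum(_xlnx(x) + np.where(x > 0, x * ln_g, 0.0)))
    return total


def direct_gibbs_flash(z, T, params, n_starts=12, seed=0):
    """Equilibrium split of feed z by direct Gibbs minimization.

    Minimizes dG_mix/RT over the phase-II component mole numbers n2 (bounded
    by 0 <= n2 <= z) with analytic gradient d(dG)/dn2_i = ln(x2_i g2_i) -
    ln(x1_i g1_i), from several random interior starts. Returns
    (x_I, x_II, L_II) with phase I the water-rich phase, or None if every
    start collapses to a single phase.
    """
    z = np.asarray(z, float)
    n = z.size
    eps = 1e-12

    def fun_grad(n2):
        n2 = np.clip(n2, eps, z - eps)
        n1 = z - n2
        L = n2.sum()
        x2 = n2 / n2.sum()
        x1 = n1 / n1.sum()
        g1 = ln_activity_coefficients(x1, T, params)
        g2 = ln_activity_coefficients(x2, T, params)
        val = gibbs_of_split([x1, x2], [1.0 - L, L], T, params)
        grad = (np.log(x2) + g2) - (np.log(x1) + g1)
        return val, grad

    rng = np.random.default_rng(seed)
    best = None
    # vertex-biased starts catch splits where one phase is small and rich
    # in a single component; purely random interior starts rarely reach them
    start_list = []
    for k in range(n):
        for f in (0.02, 0.98):
            frac = np.full(n, f)
            frac[k] = 1.0 - f
            start_list.append(frac)
    start_list += [rng.uniform(0.05, 0.95, size=n) for _ in range(n_starts)]
    for frac in start_list:
        n2_0 = np.clip(frac * z, eps, z - eps)
        sol = minimize(
            fun_grad,
            n2_0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(eps, zi - eps) for zi in z],
            options={"ftol": 1e-18, "gtol": 1e-14, "maxiter": 2000},
        )
        if best is None or sol.fun < best.fun:
            best = sol
    n2 = np.clip(best.x, eps, z - eps)
    L = n2.sum()
    x2 = n2 / n2.sum()
    n1 = z - n2
    x1 = n1 / n1.sum()
    if np.max(np.abs(x1 - x2)) < 1e-4:
        return None  # single phase
    if x1[0] >= x2[0]:
        return x1, x2, float(L)
    return x2, x1, float(1.0 - L)


# --------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def binary_demix():
    """Symmetric demixing binary: tau12 = tau21 = 3, alpha = 0.2."""
    return make_demixing_system("binary_symmetric")


@pytest.fixture(scope="session")
def broth_system():
    """Water/solute/ester system with solute partitioning to the ester."""
    return make_demixing_system("ternary_broth_like")


@pytest.fixture(scope="session")
def type1_system():
    return make_demixing_system("ternary_type1")


@pytest.fixture(scope="session")
def ideal_ternary():
    comps = ComponentSet(("water", "solute", "ester"), (18.015, 88.11, 172.26))
    alpha = np.full((3, 3), 0.3)
    np.fill_diagonal(alpha, 0.0)
    return comps, NrtlParameterSet(comps, np.zeros((3, 3)), alpha)
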