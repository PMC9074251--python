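"""Isothermal two-liquid-phase flash and binodal-curve tracing.

The flash solves the phase equations

    x_i^I  = z_i / (1 + (K_i - 1) L^II)
    x_i^II = K_i x_i^I
    K_i    = gamma_i^I / gamma_i^II

by successive substitution on K with an inner one-dimensional
Rachford-Rice solve for the liquid-II fraction L^II. Phase I is the
aqueous (water-rich) phase and phase II the organic (solvent-rich) phase,
resolved by the mole fraction of the first component (water by convention),
ties broken on the last component (solvent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .nrtl import (
    NrtlParameterSet,
    PhaseSplit,
    _check_composition,
    ln_activity_coefficients,
    stability_test,
)

__all__ = ["FlashResult", "TieLine", "lle_flash", "binodal_curve"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TieLine:
    """Coexisting organic/aqueous phase compositions at temperature T."""

    x_org: np.ndarray
    x_aq: np.ndarray
    T: float = 298.15

    def __post_init__(self) -> None:
        for name in ("x_org", "x_aq"):
            x = np.asarray(getattr(self, name), dtype=float)
            if abs(x.sum() - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1 within 1e-6, got {x.sum()!r}")
            x.setflags(write=False)
            object.__setattr__(self, name, x)
        if np.linalg.norm(self.x_org - self.x_aq) <= 1e-4:
            raise ValueError("tie-line phases coincide (distance <= 1e-4)")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.x_org - self.x_aq))

    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.x_org + self.x_aq)


@dataclass(frozen=True)
class FlashResult:
    """Converged (or flagged) result of an isothermal two-phase flash."""

    x_I: np.ndarray  # aqueous phase
    x_II: np.ndarray  # organic phase
    L_II: float  # organic phase mole fraction of total
    K: np.ndarray
    gamma_I: np.ndarray
    gamma_II: np.ndarray
    converged: bool
    iterations: int
    iso_activity_residual: float
    T: float = 298.15

    @property
    def two_phase(self) -> bool:
        return 0.0 < self.L_II < 1.0 and np.linalg.norm(self.x_I - self.x_II) > 1e-4

    def split(self) -> PhaseSplit:
        return PhaseSplit(
            phases=((self.x_I, 1.0 - self.L_II), (self.x_II, self.L_II)), T=self.T
        )

    def tieline(self) -> TieLine:
        if not self.two_phase:
            raise ValueError("single-phase flash result has no tie-line")
        return TieLine(x_org=self.x_II, x_aq=self.x_I, T=self.T)


def _order_phases(
    xa: np.ndarray, xb: np.ndarray, la: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (x_I aqueous, x_II organic, L_II): phase I has more of
    component 0 (water); ties broken by less of the last component."""
    if xa[0] > xb[0] or (xa[0] == xb[0] and xa[-1] < xb[-1]):
        return xa, xb, 1.0 - la
    return xb, xa, la


def _rachford_rice(z: np.ndarray, K: np.ndarray) -> Optional[float]:
    """Solve sum_i z_i (K_i - 1)/(1 + (K_i - 1) L) = 0 for L in (0, 1).

    The function is strictly decreasing in L wherever defined; returns None
    when no root exists inside the open interval (single-phase indication).
    """

    def f(L: float) -> float:
        return float(np.sum(z * (K - 1.0) / (1.0 + (K - 1.0) * L)))

    # restrict to the pole-free interval around (0, 1)
    lo, hi = 0.0, 1.0
    with np.errstate(divide="ignore"):
        poles = 1.0 / (1.0 - K[np.abs(K - 1.0) > 1e-14])
    for p in poles:
        if 0.0 < p < 1.0:  # cannot happen for K > 0, kept for safety
            continue
    f_lo, f_hi = f(lo), f(hi)
    if f_lo <= 0.0 or f_hi >= 0.0:
        return None
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200))


def _single_phase_result(
    z: np.ndarray, T: float, params: NrtlParameterSet, iterations: int = 0
) -> FlashResult:
    gamma = np.exp(ln_activity_coefficients(z, T, params))
    return FlashResult(
        x_I=z,
        x_II=z.copy(),
        L_II=0.0,
        K=np.ones_like(z),
        gamma_I=gamma,
        gamma_II=gamma.copy(),
        converged=True,
        iterations=iterations,
        iso_activity_residual=0.0,
        T=T,
    )


def lle_flash(
    z: Sequence[float],
    T: float,
    params: NrtlParameterSet,
    init: Optional[Sequence[float]] = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    max_restarts: int = 4,
) -> FlashResult:
    """Two-liquid-phase equilibrium flash of feed z at temperature T.

    Returns a single-phase result (L_II = 0) if the feed passes the
    tangent-plane stability test. Otherwise iterates K <- gamma^I/gamma^II
    with an inner Rachford-Rice solve until the iso-activity residual
    max |x^I gamma^I - x^II gamma^II| falls below ``tol``. Trivial
    convergence (both phases equal for an unstable feed) triggers a
    perturbed restart.
    """
    z = _check_composition(np.asarray(z, float))
    if z.shape != (params.n,):
        raise ValueError("feed dimension does not match parameter set")

    if init is None:
        stab = stability_test(z, T, params)
        if stab.stable:
            return _single_phase_result(z, T, params)
        trial = stab.trial
    else:
        trial = np.asarray(init, float)

    rng = np.random.default_rng(0)
    for restart in range(max_restarts + 1):
        result = _flash_from_trial(z, T, params, trial, max_iter, tol)
        if result is not None:
            return result
        # trivial or failed: perturb the trial phase and retry
        logger.debug("flash restart %d for feed %s", restart + 1, z)
        trial = np.clip(trial + rng.normal(0.0, 0.05, size=z.size), 1e-6, None)
        trial = trial / trial.sum()
    raise RuntimeError(
        f"lle_flash: trivial solution persisted after {max_restarts} restarts "
        f"for feed {z} at T={T}"
    )


def _flash_from_trial(
    z: np.ndarray,
    T: float,
    params: NrtlParameterSet,
    trial: np.ndarray,
    max_iter: int,
    tol: float,
) -> Optional[FlashResult]:
    ln_g_z = ln_activity_coefficients(z, T, params)
    ln_g_t = ln_activity_coefficients(trial, T, params)
    # initial K assuming trial is the incipient second phase
    with np.errstate(divide="ignore"):
        K = np.exp(ln_g_z - ln_g_t)
    K = np.clip(K, 1e-10, 1e10)

    prev_dK = None
    damp = 1.0
    xa = xb = z
    L = 0.5
    for it in range(1, max_iter + 1):
        L_root = _rachford_rice(z, K)
        if L_root is None:
            # K drifted to single-phase territory
            return _single_phase_result(z, T, params, iterations=it)
        L = L_root
        xa = z / (1.0 + (K - 1.0) * L)  # phase A ("I" of the iteration)
        xb = K * xa
        xa = np.clip(xa, 0.0, None)
        xb = np.clip(xb, 0.0, None)
        xa = xa / xa.sum()
        xb = xb / xb.sum()
        ln_ga = ln_activity_coefficients(xa, T, params)
        ln_gb = ln_activity_coefficients(xb, T, params)
        K_new = np.clip(np.exp(ln_ga - ln_gb), 1e-10, 1e10)
        dK = np.log(K_new) - np.log(K)
        if prev_dK is not None and float(dK @ prev_dK) < 0:
            damp = 0.5  # oscillation detected
        K = np.exp(np.log(K) + damp * dK)
        prev_dK = dK
        res = float(np.max(np.abs(xa * np.exp(ln_ga) - xb * np.exp(ln_gb))))
        if res < tol and np.max(np.abs(dK)) < 1e-10:
            if np.max(np.abs(xa - xb)) < 1e-4:
                return None  # trivial solution
            x_I, x_II, L_II = _order_phases(xa, xb, 1.0 - L)
            g_I = np.exp(ln_activity_coefficients(x_I, T, params))
            g_II = np.exp(ln_activity_coefficients(x_II, T, params))
            return FlashResult(
                x_I=x_I,
                x_II=x_II,
                L_II=L_II,
                K=np.where(x_I > 0, x_II / np.where(x_I > 0, x_I, 1.0), np.inf),
                gamma_I=g_I,
                gamma_II=g_II,
                converged=True,
                iterations=it,
                iso_activity_residual=res,
                T=T,
            )
    # non-convergence: flagged, never silent
    x_I, x_II, L_II = _order_phases(xa, xb, 1.0 - L)
    logger.warning("lle_flash failed to converge in %d iterations", max_iter)
    return FlashResult(
        x_I=x_I,
        x_II=x_II,
        L_II=L_II,
        K=K,
        gamma_I=np.exp(ln_activity_coefficients(x_I, T, params)),
        gamma_II=np.exp(ln_activity_coefficients(x_II, T, params)),
        converged=False,
        iterations=max_iter,
        iso_activity_residual=float("nan"),
        T=T,
    )


def binodal_curve(
    T: float,
    params: NrtlParameterSet,
    n_lines: int = 10,
    solute_index: int = 1,
    step: float = 0.01,
    min_length: float = 1e-3,
    max_steps: int = 400,
) -> list[TieLine]:
    """Trace tie-lines from the immiscible binary edge toward the plait point.

    Feeds are marched from the solute-free binary (components 0 and last)
    midpoint, adding solute along the previous tie-line midpoint. Marching
    stops at ``max_steps``, when a feed goes single-phase, or when the
    tie-line length drops below ``min_length`` (plait-point vicinity).
    Returns up to ``n_lines`` tie-lines ordered by increasing solute content.
    """
    n = params.n
    z0 = np.zeros(n)
    z0[0] = 0.5
    z0[-1] = 0.5
    stab = stability_test(z0, T, params)
    if stab.stable:
        logger.warning("binodal_curve: binary edge is fully miscible; no binodal")
        return []

    lines: list[TieLine] = []
    z = z0
    e_solute = np.zeros(n)
    e_solute[solute_index] = 1.0
    for _ in range(max_steps):
        try:
            fr = lle_flash(z, T, params)
        except RuntimeError:
            break
        if not fr.two_phase or not fr.converged:
            break
        if np.linalg.norm(fr.x_I - fr.x_II) < min_length:
            break
        lines.append(fr.tieline())
        mid = fr.tieline().midpoint()
        z = mid + step * e_solute
        z = np.clip(z, 0.0, None)
        z = z / z.sum()
    lines.sort(key=lambda tl: tl.midpoint()[solute_index])
    if n_lines > 0 and len(lines) > n_lines:
        # keep the solute-free edge line, spread the rest over the curve
        idx = np.unique(np.round(np.linspace(0, len(lines) - 1, n_lines)).astype(int))
        lines = [lines[i] for i in idx]
    return lines
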