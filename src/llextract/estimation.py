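"""Tie-line-constrained NRTL parameter estimation by the non-iterative
K-value method.

Conventional K-value regression of liquid-liquid equilibrium data solves a
flash iteratively inside every objective evaluation. Here the iteration is
eliminated by exploiting tie-line geometry: the feed z lies on the measured
tie-line (collinearity of z - x^II with x^I - x^II), so fixing the feed
content of one component determines the rest, and the liquid-II fraction
follows from the lever rule on Euclidean distances,

    L^II = d(x^I, z) / d(x^I, x^II).

With z and L^II fixed from the data, the phase equations

    x_i^I = z_i / (1 + (K_i - 1) L^II),   x_i^II = K_i x_i^I,
    K_i   = gamma_i^I / gamma_i^II

are evaluated in one shot at the measured compositions, and the parameters
are chosen to minimize the deviation between computed and measured tie-line
compositions, subject to the fitted model actually demixing at each feed
with a Gibbs energy of mixing below the single-phase value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .components import ComponentSet
from .flash import TieLine, lle_flash
from .nrtl import (
    NrtlParameterSet,
    PhaseSplit,
    gibbs_mixing_reduced,
    ln_activity_coefficients,
)

__all__ = [
    "TieLineDataset",
    "FitConfig",
    "FitResult",
    "EstimationError",
    "feed_on_tieline",
    "lever_fraction",
    "kvalue_residual",
    "estimate_nrtl",
]

logger = logging.getLogger(__name__)

#: residual magnitude substituted when the phase-equation denominator
#: 1 + (K-1) L^II is non-positive (keeps the objective finite for optimizers)
PENALTY_RESIDUAL = 10.0


class EstimationError(RuntimeError):
    """No feasible parameter set found across all multistarts."""


@dataclass(frozen=True)
class TieLineDataset:
    """A set of isothermal tie-lines with a stated measurement uncertainty."""

    components: ComponentSet
    tielines: tuple[TieLine, ...]
    T: float = 298.15
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        tls = tuple(self.tielines)
        for tl in tls:
            if abs(tl.T - self.T) > 1e-9:
                raise ValueError("all tie-lines in a dataset must share T")
        object.__setattr__(self, "tielines", tls)

    def __len__(self) -> int:
        return len(self.tielines)


def _resolve_phases(tieline: TieLine) -> tuple[np.ndarray, np.ndarray]:
    """(x_I aqueous, x_II organic) regardless of stored orientation.

    Phase I is the one richer in component 0 (water by convention); ties
    broken by the last component (solvent)."""
    a, b = tieline.x_aq, tieline.x_org
    if a[0] > b[0] or (a[0] == b[0] and a[-1] < b[-1]):
        return a, b
    return b, a


def feed_on_tieline(tieline: TieLine, z1: float) -> np.ndarray:
    """Feed composition on the tie-line with component-1 content z1.

    Collinearity z = x^II + t (x^I - x^II) fixes every component from a
    single one; the result sums to one exactly because both endpoints do.
    z1 must lie strictly between the two measured values x_1^I and x_1^II.
    """
    x_I, x_II = _resolve_phases(tieline)
    lo, hi = sorted((x_I[0], x_II[0]))
    if not lo < z1 < hi:
        raise ValueError(
            f"z1={z1} must lie strictly between the phase values ({lo}, {hi})"
        )
    t = (z1 - x_II[0]) / (x_I[0] - x_II[0])
    z = x_II + t * (x_I - x_II)
    return z


def lever_fraction(tieline: TieLine, z: Sequence[float], tol: float = 1e-8) -> float:
    """Liquid-II (organic) fraction of feed z by the lever rule.

    L^II = d(x^I, z) / d(x^I, x^II) with Euclidean distances; requires z
    collinear with the tie-line within ``tol`` and between the endpoints.
    """
    z = np.asarray(z, float)
    x_I, x_II = _resolve_phases(tieline)
    d = x_II - x_I
    t = float((z - x_I) @ d / (d @ d))
    resid = float(np.linalg.norm(z - (x_I + t * d)))
    if resid > tol:
        raise ValueError(
            f"feed is not on the tie-line (collinearity residual {resid:.3e})"
        )
    if not -tol <= t <= 1.0 + tol:
        raise ValueError(f"feed lies outside the tie-line segment (t={t})")
    L = float(np.linalg.norm(z - x_I) / np.linalg.norm(x_II - x_I))
    return min(max(L, 0.0), 1.0)


def _midpoint_z1(tieline: TieLine) -> float:
    x_I, x_II = _resolve_phases(tieline)
    return 0.5 * (x_I[0] + x_II[0])


class ComputedTieLine(NamedTuple):
    """One-shot phase-equation output; unlike TieLine, the two computed
    phases may coincide (e.g. under ideal parameters)."""

    x_org: np.ndarray
    x_aq: np.ndarray
    T: float


def kvalue_residual(
    params: NrtlParameterSet,
    tieline: TieLine,
    z1: Optional[float] = None,
) -> tuple[ComputedTieLine, np.ndarray]:
    """Non-iterative phase-equation residual for one measured tie-line.

    The feed z (via ``z1``, default the midpoint rule) and lever fraction
    L^II come from measured geometry; K is evaluated once at the measured
    compositions; the phase equations then yield computed compositions whose
    deviation from the measurements is the residual (aqueous block first,
    organic second, length 2N).
    """
    x_I, x_II = _resolve_phases(tieline)
    if z1 is None:
        z1 = _midpoint_z1(tieline)
    z = feed_on_tieline(tieline, z1)
    L = lever_fraction(tieline, z)
    T = tieline.T

    ln_g_I = ln_activity_coefficients(x_I, T, params)
    ln_g_II = ln_activity_coefficients(x_II, T, params)
    K = np.exp(ln_g_I - ln_g_II)

    denom = 1.0 + (K - 1.0) * L
    if np.any(denom <= 0.0):
        logger.debug("kvalue_residual: non-positive denominator; penalizing")
        n = params.n
        resid = np.full(2 * n, PENALTY_RESIDUAL)
        return ComputedTieLine(x_org=x_II.copy(), x_aq=x_I.copy(), T=T), resid

    xc_I = z / denom
    xc_II = K * xc_I
    s_I, s_II = xc_I.sum(), xc_II.sum()
    if abs(s_I - 1.0) > 1e-6 or abs(s_II - 1.0) > 1e-6:
        logger.debug(
            "kvalue_residual: renormalizing computed phases (sums %.6f, %.6f)",
            s_I,
            s_II,
        )
    xc_I = xc_I / s_I
    xc_II = xc_II / s_II
    resid = np.concatenate([xc_I - x_I, xc_II - x_II])
    return ComputedTieLine(x_org=xc_II, x_aq=xc_I, T=T), resid


@dataclass
class FitConfig:
    """Options for :func:`estimate_nrtl`.

    ``fit_pairs`` selects which (i, j) component pairs get free tau_ij and
    tau_ji; default all pairs. alpha is fixed at ``alpha_default`` unless
    ``fit_alpha``; bounds follow common LLE practice.
    """

    fit_pairs: Optional[Sequence[tuple[int, int]]] = None
    fit_alpha: bool = False
    alpha_default: float = 0.2
    tau_bounds: tuple[float, float] = (-5.0, 12.0)
    alpha_bounds: tuple[float, float] = (0.2, 0.47)
    n_starts: int = 16
    seed: int = 42
    z1: Optional[float] = None  # None -> midpoint rule per tie-line
    gibbs_penalty_weight: float = 10.0
    #: extra multistart batches (fresh Latin-hypercube draws) tried when no
    #: Gibbs-feasible candidate emerges from the first batch + refinement
    max_batches: int = 3
    #: coarse screen realizing the Gibbs-minimum constraint: the model's
    #: equilibrium split at each measured feed must reproduce the measured
    #: phases to within this mole-fraction tolerance (an iso-activity pair
    #: that is not the minimizing split fails it)
    split_match_tol: float = 0.05
    initial: Optional[NrtlParameterSet] = None  # extra warm start


@dataclass(frozen=True)
class FitResult:
    params: NrtlParameterSet
    objective: float  # RMS composition deviation
    per_tieline_residuals: np.ndarray  # (n_tielines, 2N)
    gibbs_feasible: tuple[bool, ...]
    n_starts: int
    seed: int

    def predicted_tielines(self, data: TieLineDataset) -> list[ComputedTieLine]:
        """Model tie-lines at each measured feed, for predicted-vs-measured
        overlays on a ternary diagram."""
        out = []
        for tl in data.tielines:
            z1 = _midpoint_z1(tl)
            z = feed_on_tieline(tl, z1)
            fr = lle_flash(z, data.T, self.params)
            out.append(ComputedTieLine(x_org=fr.x_II, x_aq=fr.x_I, T=data.T))
        return out


def _immiscible_pairs(data: TieLineDataset, tol: float = 0.02) -> set[frozenset]:
    """Binary pairs the data show as demixing: some tie-line is essentially
    binary in (i, j) in both phases (other components below ``tol``)."""
    n = data.components.n
    out: set[frozenset] = set()
    for tl in data.tielines:
        for i in range(n):
            for j in range(i + 1, n):
                others = [k for k in range(n) if k not in (i, j)]
                if (
                    sum(tl.x_org[k] for k in others) < tol
                    and sum(tl.x_aq[k] for k in others) < tol
                ):
                    out.add(frozenset((i, j)))
    return out


_CURV_GRID = np.linspace(0.01, 0.99, 99)


def _binary_curvature_min(tau_ij: float, tau_ji: float, alpha: float) -> float:
    """Minimum d2(g_mix)/dx2 of the i-j binary over composition; negative
    values signal a spinodal (the binary demixes)."""
    x1 = _CURV_GRID
    x2 = 1.0 - x1
    G12 = np.exp(-alpha * tau_ij)
    G21 = np.exp(-alpha * tau_ji)
    g = (
        x1 * np.log(x1)
        + x2 * np.log(x2)
        + x1 * x2 * (tau_ji * G21 / (x1 + x2 * G21) + tau_ij * G12 / (x2 + x1 * G12))
    )
    h = x1[1] - x1[0]
    return float(np.min(np.diff(g, 2))) / h**2


def _pair_list(n: int, fit_pairs: Optional[Sequence[tuple[int, int]]]):
    if fit_pairs is None:
        return [(i, j) for i in range(n) for j in range(i + 1, n)]
    return [tuple(sorted(p)) for p in fit_pairs]


def _unpack(
    theta: np.ndarray,
    template: NrtlParameterSet,
    pairs: Sequence[tuple[int, int]],
    fit_alpha: bool,
) -> NrtlParameterSet:
    tau = np.array(template.tau)
    alpha = np.array(template.alpha)
    k = 0
    for i, j in pairs:
        tau[i, j] = theta[k]
        tau[j, i] = theta[k + 1]
        k += 2
    if fit_alpha:
        for i, j in pairs:
            alpha[i, j] = alpha[j, i] = theta[k]
            k += 1
    return NrtlParameterSet(
        components=template.components, tau=tau, alpha=alpha, T_ref=template.T_ref
    )


def _gibbs_feasibility(
    params: NrtlParameterSet,
    data: TieLineDataset,
    z1: Optional[float],
    split_match_tol: float = 0.05,
) -> tuple[bool, ...]:
    """Per tie-line: is the measured split the model's Gibbs minimum?

    Requires (a) the model demixes at the measured feed with a mixing Gibbs
    energy below the homogeneous value, and (b) the minimizing split matches
    the measured phase compositions to within ``split_match_tol`` — a fit
    that merely puts an iso-activity pair at the measured compositions while
    its true equilibrium lies elsewhere is rejected."""
    flags = []
    for tl in data.tielines:
        x_I, x_II = _resolve_phases(tl)
        z = feed_on_tieline(tl, z1 if z1 is not None else _midpoint_z1(tl))
        try:
            fr = lle_flash(z, data.T, params)
        except RuntimeError:
            flags.append(False)
            continue
        if not (fr.converged and fr.two_phase):
            flags.append(False)
            continue
        g_split = gibbs_mixing_reduced(fr.split(), params)
        g_feed = gibbs_mixing_reduced(PhaseSplit.single(z, data.T), params)
        dev = max(
            float(np.max(np.abs(fr.x_I - x_I))), float(np.max(np.abs(fr.x_II - x_II)))
        )
        flags.append(g_split <= g_feed + 1e-12 and dev <= split_match_tol)
    return tuple(flags)


def estimate_nrtl(data: TieLineDataset, config: Optional[FitConfig] = None) -> FitResult:
    """Fit NRTL parameters to tie-line data by the non-iterative K-value
    method with multistart local least squares.

    The objective is the unweighted RMS of :func:`kvalue_residual` over all
    components, both phases and all tie-lines. Candidates are ranked with a
    penalty for tie-lines where the fitted model fails the Gibbs demixing
    check; the best feasible candidate is returned.
    """
    config = config or FitConfig()
    if len(data) < 2:
        raise ValueError("at least 2 tie-lines are required for a fit")
    n = data.components.n
    pairs = _pair_list(n, config.fit_pairs)
    n_theta = 2 * len(pairs) + (len(pairs) if config.fit_alpha else 0)

    alpha0 = np.zeros((n, n))
    for i, j in pairs:
        alpha0[i, j] = alpha0[j, i] = config.alpha_default
    template = NrtlParameterSet(
        components=data.components, tau=np.zeros((n, n)), alpha=alpha0, T_ref=data.T
    )

    lo = np.r_[
        np.full(2 * len(pairs), config.tau_bounds[0]),
        np.full(len(pairs) if config.fit_alpha else 0, config.alpha_bounds[0]),
    ]
    hi = np.r_[
        np.full(2 * len(pairs), config.tau_bounds[1]),
        np.full(len(pairs) if config.fit_alpha else 0, config.alpha_bounds[1]),
    ]

    sampler = qmc.LatinHypercube(d=n_theta, seed=config.seed)
    starts = list(qmc.scale(sampler.random(config.n_starts), lo, hi))
    if config.initial is not None:
        theta0 = []
        for i, j in pairs:
            theta0 += [config.initial.tau[i, j], config.initial.tau[j, i]]
        if config.fit_alpha:
            theta0 += [config.initial.alpha[i, j] for i, j in pairs]
        starts.insert(0, np.clip(np.asarray(theta0, float), lo, hi))

    # the data fix the diagram type: pairs with no essentially-binary
    # tie-line must remain miscible, which excludes the estimator's
    # spurious iso-activity solutions that open extra miscibility gaps
    demixing = _immiscible_pairs(data)
    miscible_pairs = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if frozenset((i, j)) not in demixing
    ]

    def edge_penalties(p: NrtlParameterSet) -> np.ndarray:
        pens = []
        for i, j in miscible_pairs:
            curv = _binary_curvature_min(p.tau[i, j], p.tau[j, i], p.alpha[i, j])
            pens.append(max(0.0, -curv))
        return np.asarray(pens)

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = _unpack(theta, template, pairs, config.fit_alpha)
        blocks = [kvalue_residual(p, tl, config.z1)[1] for tl in data.tielines]
        return np.concatenate(blocks + [edge_penalties(p)])

    # measured geometry reused by the penalized refinement objective
    feeds = [
        feed_on_tieline(tl, config.z1 if config.z1 is not None else _midpoint_z1(tl))
        for tl in data.tielines
    ]
    measured = [_resolve_phases(tl) for tl in data.tielines]

    def split_deviation(p: NrtlParameterSet, idx: int) -> float:
        """Max |equilibrium split - measured split| for one tie-line; 1.0
        when the model fails to demix at the measured feed. The flash is
        initialized from its own stability test (not the measured phases),
        so a metastable iso-activity pair at the data cannot mask a deeper
        split elsewhere."""
        x_I, x_II = measured[idx]
        try:
            fr = lle_flash(feeds[idx], data.T, p, max_iter=200, max_restarts=1)
        except RuntimeError:
            return 1.0
        if not (fr.converged and fr.two_phase):
            return 1.0
        return max(
            float(np.max(np.abs(fr.x_I - x_I))),
            float(np.max(np.abs(fr.x_II - x_II))),
        )

    pen_tol = 0.5 * config.split_match_tol
    pen_scale = np.sqrt(config.gibbs_penalty_weight)

    def penalized_residuals(theta: np.ndarray) -> np.ndarray:
        """Shortcut residuals plus hinge penalties that activate when the
        fitted model's actual equilibrium drifts off the measured split —
        the operational form of the Gibbs-minimum estimation constraint."""
        p = _unpack(theta, template, pairs, config.fit_alpha)
        blocks = [kvalue_residual(p, tl, config.z1)[1] for tl in data.tielines]
        pens = [
            pen_scale * max(0.0, split_deviation(p, i) - pen_tol)
            for i in range(len(data.tielines))
        ]
        return np.concatenate(blocks + [np.asarray(pens), edge_penalties(p)])

    candidates: list[tuple[float, np.ndarray, FitResult]] = []

    def run_start(theta_start: np.ndarray) -> Optional[FitResult]:
        try:
            sol = least_squares(
                residuals, theta_start, bounds=(lo, hi), xtol=1e-14, ftol=1e-14,
                gtol=1e-12, max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - optimizer robustness
            logger.debug("start failed: %s", exc)
            return None
        p = _unpack(sol.x, template, pairs, config.fit_alpha)
        per_tl = np.array(
            [kvalue_residual(p, tl, config.z1)[1] for tl in data.tielines]
        )
        rms = float(np.sqrt(np.mean(per_tl**2)))
        feas = _gibbs_feasibility(p, data, config.z1, config.split_match_tol)
        result = FitResult(
            params=p,
            objective=rms,
            per_tieline_residuals=per_tl,
            gibbs_feasible=feas,
            n_starts=config.n_starts,
            seed=config.seed,
        )
        # penalized score ranks candidates when the hard screen fails
        score = rms + config.gibbs_penalty_weight * rms * sum(
            not f for f in feas
        )
        candidates.append((score, sol.x, result))
        return result

    def evaluate(theta: np.ndarray) -> FitResult:
        """Screen a parameter vector as-is (no further optimization)."""
        p = _unpack(theta, template, pairs, config.fit_alpha)
        per_tl = np.array(
            [kvalue_residual(p, tl, config.z1)[1] for tl in data.tielines]
        )
        rms = float(np.sqrt(np.mean(per_tl**2)))
        feas = _gibbs_feasibility(p, data, config.z1, config.split_match_tol)
        result = FitResult(
            params=p,
            objective=rms,
            per_tieline_residuals=per_tl,
            gibbs_feasible=feas,
            n_starts=config.n_starts,
            seed=config.seed,
        )
        score = rms + config.gibbs_penalty_weight * rms * sum(
            not f for f in feas
        )
        candidates.append((score, theta, result))
        return result

    def best_feasible() -> Optional[FitResult]:
        feasible = [r for _, _, r in candidates if all(r.gibbs_feasible)]
        if not feasible:
            return None
        return min(feasible, key=lambda r: r.objective)

    def refine_top_candidates() -> None:
        # refinement driven by the penalized objective: the unpenalized
        # shortcut can have spurious minima whose iso-activity pairs sit at
        # the measured compositions without being the stable split, so
        # re-optimize the most promising candidates with the Gibbs-split
        # hinge penalties active
        top = sorted(candidates, key=lambda c: c[0])[:3]
        for _, theta, _ in top:
            try:
                sol = least_squares(
                    penalized_residuals,
                    theta,
                    bounds=(lo, hi),
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-10,
                    max_nfev=400,
                    diff_step=1e-4,
                )
            except Exception as exc:  # pragma: no cover
                logger.debug("penalized refinement failed: %s", exc)
                continue
            evaluate(sol.x)
            if best_feasible() is not None:
                return

    best: Optional[FitResult] = None
    for batch in range(max(1, config.max_batches)):
        if batch == 0:
            batch_starts = starts
        else:
            # fresh quasi-random draw; some noise realizations need more
            # coverage before a Gibbs-feasible basin is hit
            sampler = qmc.LatinHypercube(
                d=n_theta, seed=(config.seed + 104729 * batch) % 2**31
            )
            batch_starts = list(qmc.scale(sampler.random(config.n_starts), lo, hi))
            logger.info(
                "estimate_nrtl: no feasible candidate yet, batch %d", batch + 1
            )
        for theta_start in batch_starts:
            run_start(theta_start)
        best = best_feasible()
        if best is None and candidates:
            refine_top_candidates()
            best = best_feasible()
        if best is not None:
            break
    if best is not None:
        return best
    if candidates:
        worst = min(candidates, key=lambda c: c[0])[2]
        raise EstimationError(
            "no Gibbs-feasible parameter set found across "
            f"{len(candidates)} starts; best infeasible objective "
            f"{worst.objective:.4g} with feasibility {worst.gibbs_feasible}"
        )
    raise EstimationError("all optimizer starts failed")
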