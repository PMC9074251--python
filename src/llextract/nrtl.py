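"""Multicomponent NRTL activity coefficients, Gibbs energy of mixing, and
phase-stability analysis.

The non-random two-liquid (NRTL) model expresses the excess Gibbs energy of a
liquid mixture through binary interaction parameters tau_ij and non-randomness
parameters alpha_ij:

    G^E / (n R T) = sum_i x_i * (sum_j tau_ji G_ji x_j) / (sum_k G_ki x_k),
    G_ij = exp(-alpha_ij tau_ij),  G_ii = 1,  tau_ii = 0.

Activity coefficients follow as the mole-number derivative of n G^E/RT:

    ln gamma_i = (sum_j tau_ji G_ji x_j) / (sum_k G_ki x_k)
               + sum_j x_j G_ij / (sum_k G_kj x_k)
                 * (tau_ij - (sum_m x_m tau_mj G_mj) / (sum_k G_kj x_k))

The dimensionless Gibbs energy of mixing of a (possibly multiphase) liquid,

    dG_mix/RT = sum_phases sum_i L^k x_i^k (ln x_i^k + ln gamma_i^k),

must be minimal at equilibrium; :func:`stability_test` checks a candidate
single-phase composition against all two-phase perturbations via the tangent
plane distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .components import ComponentSet

__all__ = [
    "NrtlParameterSet",
    "PhaseSplit",
    "activity_coefficients",
    "ln_activity_coefficients",
    "excess_gibbs_reduced",
    "gibbs_mixing_reduced",
    "stability_test",
    "StabilityResult",
]

logger = logging.getLogger(__name__)

_SIMPLEX_TOL = 1e-9


def _check_composition(x: np.ndarray, tol: float = _SIMPLEX_TOL) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12):
        raise ValueError(f"negative mole fraction in {x}")
    if abs(x.sum() - 1.0) > tol:
        raise ValueError(f"mole fractions must sum to 1, got sum={x.sum()!r}")
    return np.clip(x, 0.0, None)


@dataclass(frozen=True)
class NrtlParameterSet:
    """NRTL binary interaction (tau) and non-randomness (alpha) matrices.

    tau may be temperature dependent through the two-constant form
    tau_ij(T) = a_ij + b_ij / T; the plain ``tau`` matrix is the value at
    ``T_ref``. Invariants: tau_ii = 0, alpha symmetric with zero diagonal and
    entries in [0, 1].
    """

    components: ComponentSet
    tau: np.ndarray
    alpha: np.ndarray
    T_ref: float = 298.15
    #: optional temperature dependence tau_ij(T) = a_ij + b_ij/T
    tau_a: Optional[np.ndarray] = None
    tau_b: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        n = self.components.n
        tau = np.array(self.tau, dtype=float)
        alpha = np.array(self.alpha, dtype=float)
        if tau.shape != (n, n) or alpha.shape != (n, n):
            raise ValueError(
                f"tau/alpha must be {n}x{n} for components {self.components.names}"
            )
        if np.any(np.abs(np.diag(tau)) > 0):
            raise ValueError("tau diagonal must be zero")
        if np.any(np.abs(np.diag(alpha)) > 0):
            raise ValueError("alpha diagonal must be zero")
        if not np.allclose(alpha, alpha.T, atol=1e-12):
            raise ValueError("alpha must be symmetric")
        if np.any(alpha < 0) or np.any(alpha > 1):
            raise ValueError("alpha entries must lie in [0, 1]")
        if self.T_ref <= 0:
            raise ValueError("T_ref must be positive (kelvin)")
        tau.setflags(write=False)
        alpha.setflags(write=False)
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "alpha", alpha)
        for name in ("tau_a", "tau_b"):
            m = getattr(self, name)
            if m is not None:
                m = np.array(m, dtype=float)
                if m.shape != (n, n):
                    raise ValueError(f"{name} must be {n}x{n}")
                m.setflags(write=False)
                object.__setattr__(self, name, m)

    @property
    def n(self) -> int:
        return self.components.n

    def tau_at(self, T: float) -> np.ndarray:
        """tau evaluated at temperature T (kelvin)."""
        if T <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.tau_a is not None and self.tau_b is not None:
            return self.tau_a + self.tau_b / T
        return self.tau

    def replace_tau(self, tau: np.ndarray) -> "NrtlParameterSet":
        """New parameter set with a different (temperature-independent) tau."""
        return NrtlParameterSet(
            components=self.components, tau=tau, alpha=self.alpha, T_ref=self.T_ref
        )

    # -- pair-list (de)serialization -------------------------------------

    def to_dict(self) -> dict:
        names = self.components.names
        pairs = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                entry = {
                    "i": names[i],
                    "j": names[j],
                    "tau_ij": float(self.tau[i, j]),
                    "tau_ji": float(self.tau[j, i]),
                    "alpha": float(self.alpha[i, j]),
                }
                if self.tau_a is not None and self.tau_b is not None:
                    entry.update(
                        a_ij=float(self.tau_a[i, j]),
                        a_ji=float(self.tau_a[j, i]),
                        b_ij=float(self.tau_b[i, j]),
                        b_ji=float(self.tau_b[j, i]),
                    )
                pairs.append(entry)
        return {
            "components": list(names),
            "molar_mass": list(self.components.molar_mass),
            "T_ref_K": self.T_ref,
            "pairs": pairs,
        }

    @classmethod
    def from_dict(cls, d: dict, default_alpha: float = 0.3) -> "NrtlParameterSet":
        names = tuple(d["components"])
        comps = ComponentSet(names, tuple(d.get("molar_mass", ())))
        n = comps.n
        tau = np.zeros((n, n))
        alpha = np.zeros((n, n))
        seen = set()
        has_t_dep = any("a_ij" in p for p in d.get("pairs", []))
        tau_a = np.zeros((n, n)) if has_t_dep else None
        tau_b = np.zeros((n, n)) if has_t_dep else None
        for p in d.get("pairs", []):
            i, j = comps.index(p["i"]), comps.index(p["j"])
            tau[i, j] = p["tau_ij"]
            tau[j, i] = p["tau_ji"]
            alpha[i, j] = alpha[j, i] = p["alpha"]
            if has_t_dep:
                T_ref = float(d.get("T_ref_K", 298.15))
                tau_a[i, j] = p.get("a_ij", p["tau_ij"])
                tau_a[j, i] = p.get("a_ji", p["tau_ji"])
                tau_b[i, j] = p.get("b_ij", 0.0)
                tau_b[j, i] = p.get("b_ji", 0.0)
                tau[i, j] = tau_a[i, j] + tau_b[i, j] / T_ref
                tau[j, i] = tau_a[j, i] + tau_b[j, i] / T_ref
            seen.add(frozenset((i, j)))
        missing = [
            (names[i], names[j])
            for i in range(n)
            for j in range(i + 1, n)
            if frozenset((i, j)) not in seen
        ]
        if missing:
            logger.warning(
                "no NRTL pair data for %s; defaulting to ideal "
                "(tau=0, alpha=%.2f)", missing, default_alpha
            )
            for a, b in missing:
                i, j = comps.index(a), comps.index(b)
                alpha[i, j] = alpha[j, i] = default_alpha
        return cls(
            components=comps,
            tau=tau,
            alpha=alpha,
            T_ref=float(d.get("T_ref_K", 298.15)),
            tau_a=tau_a,
            tau_b=tau_b,
        )


@dataclass(frozen=True)
class PhaseSplit:
    """A liquid distributed over one or more phases.

    ``phases`` holds (composition, phase mole fraction) pairs; compositions
    sum to 1 and phase fractions sum to 1, both to 1e-12.
    """

    phases: tuple[tuple[np.ndarray, float], ...]
    T: float = 298.15

    def __post_init__(self) -> None:
        phases = []
        total_l = 0.0
        for x, l in self.phases:
            x = np.asarray(x, dtype=float)
            if np.any(x < 0) or np.any(x > 1):
                raise ValueError(f"compositions must be in [0,1], got {x}")
            if abs(x.sum() - 1.0) > 1e-12:
                raise ValueError(f"phase composition must sum to 1, got {x.sum()!r}")
            if not 0.0 <= l <= 1.0:
                raise ValueError(f"phase fraction must be in [0,1], got {l}")
            total_l += l
            x = x.copy()
            x.setflags(write=False)
            phases.append((x, float(l)))
        if abs(total_l - 1.0) > 1e-12:
            raise ValueError(f"phase fractions must sum to 1, got {total_l!r}")
        object.__setattr__(self, "phases", tuple(phases))

    @classmethod
    def single(cls, x: Sequence[float], T: float = 298.15) -> "PhaseSplit":
        return cls(phases=((np.asarray(x, float), 1.0),), T=T)

    def overall(self) -> np.ndarray:
        """Overall (feed) composition implied by the split."""
        return sum(l * x for x, l in self.phases)


def ln_activity_coefficients(
    x: Sequence[float], T: float, params: NrtlParameterSet
) -> np.ndarray:
    """ln gamma for all components at composition x and temperature T.

    Finite on the closed simplex: vertex values are the infinite-dilution
    limits obtained by continuity (the working equations are continuous in x
    on the closed simplex, so direct evaluation is safe).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.n,):
        raise ValueError(
            f"composition has {x.shape[0]} entries but parameter set has {params.n}"
        )
    x = _check_composition(x)
    tau = params.tau_at(T)
    G = np.exp(-params.alpha * tau)
    # S_j = sum_k G_kj x_k  (>0 always since G_jj = 1 and x on simplex)
    S = G.T @ x
    # C_j = sum_m x_m tau_mj G_mj
    C = (tau * G).T @ x
    # ln gamma_i = C_i/S_i + sum_j x_j G_ij / S_j * (tau_ij - C_j/S_j)
    ln_gamma = C / S + np.einsum("j,ij->i", x / S, G * (tau - (C / S)[None, :]))
    return ln_gamma


def activity_coefficients(
    x: Sequence[float], T: float, params: NrtlParameterSet
) -> np.ndarray:
    """NRTL activity coefficients gamma_i(x, T)."""
    return np.exp(ln_activity_coefficients(x, T, params))


def excess_gibbs_reduced(
    x: Sequence[float], T: float, params: NrtlParameterSet
) -> float:
    """Molar excess Gibbs energy G^E/RT at composition x."""
    x = _check_composition(np.asarray(x, float))
    tau = params.tau_at(T)
    G = np.exp(-params.alpha * tau)
    S = G.T @ x
    C = (tau * G).T @ x
    return float(x @ (C / S))


def _xlnx(x: np.ndarray) -> np.ndarray:
    """x ln x with the limit convention 0 ln 0 = 0."""
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def gibbs_mixing_reduced(split: PhaseSplit, params: NrtlParameterSet) -> float:
    """Dimensionless Gibbs energy of mixing dG_mix/RT of a phase split.

    For each phase k with fraction L^k: sum_i L^k x_i^k (ln x_i^k +
    ln gamma_i^k); zero-composition terms vanish by the x ln x convention.
    """
    total = 0.0
    for x, l in split.phases:
        if l == 0.0:
            continue
        ln_g = ln_activity_coefficients(x, split.T, params)
        contrib = _xlnx(x) + np.where(x > 0, x * ln_g, 0.0)
        total += l * float(contrib.sum())
    return total


@dataclass(frozen=True)
class StabilityResult:
    stable: bool
    tpd: float
    trial: Optional[np.ndarray]  # most negative-TPD composition if unstable


def _tpd(w: np.ndarray, d_feed: np.ndarray, T: float, params: NrtlParameterSet) -> float:
    """Tangent plane distance of trial composition w w.r.t. feed chemical
    potentials d_feed = ln z + ln gamma(z)."""
    ln_g = ln_activity_coefficients(w, T, params)
    pos = w > 0
    return float(np.sum(w[pos] * (np.log(w[pos]) + ln_g[pos] - d_feed[pos])))


def stability_test(
    z: Sequence[float],
    T: float,
    params: NrtlParameterSet,
    extra_starts: Iterable[Sequence[float]] = (),
    max_iter: int = 200,
    tol: float = 1e-12,
    tpd_threshold: float = -1e-8,
) -> StabilityResult:
    """Tangent-plane-distance stability test of a single liquid phase.

    Runs Michelsen-style successive substitution on unnormalized trial mole
    numbers W_i from vertex-biased starts; the feed is declared unstable if
    any converged trial has TPD below ``tpd_threshold``, in which case the
    trial composition seeds a two-phase flash.
    """
    z = _check_composition(np.asarray(z, float))
    n = params.n
    if np.count_nonzero(z) == 1:
        return StabilityResult(stable=True, tpd=0.0, trial=None)
    zz = np.clip(z, 1e-15, None)
    d_feed = np.log(zz) + ln_activity_coefficients(z, T, params)

    starts: list[np.ndarray] = []
    for i in range(n):
        v = np.full(n, 0.05 / max(n - 1, 1))
        v[i] = 0.95
        starts.append(v)
    starts.extend(np.asarray(s, float) for s in extra_starts)

    best_tpd = 0.0
    best_trial: Optional[np.ndarray] = None
    for w0 in starts:
        W = np.clip(w0, 1e-12, None)
        for _ in range(max_iter):
            w = W / W.sum()
            ln_g = ln_activity_coefficients(w, T, params)
            W_new = np.exp(d_feed - ln_g)
            if np.max(np.abs(W_new - W)) < tol:
                W = W_new
                break
            W = W_new
        w = W / W.sum()
        tpd = _tpd(w, d_feed, T, params)
        # trivial solution (w == z) carries TPD ~ 0; keep only genuine minima
        if tpd < best_tpd and np.max(np.abs(w - z)) > 1e-6:
            best_tpd = tpd
            best_trial = w
    if best_tpd < tpd_threshold:
        return StabilityResult(stable=False, tpd=best_tpd, trial=best_trial)
    return StabilityResult(stable=True, tpd=best_tpd, trial=None)
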