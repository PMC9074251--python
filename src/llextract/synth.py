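"""Synthetic tie-line data with known ground truth.

Generates demixing NRTL systems and noisy tie-line datasets shaped like
measured liquid-liquid equilibrium tables (one row per tie-line: organic and
aqueous phase mole fractions at a common temperature), so estimation and
cascade code can be exercised end to end without any external measurements.
The default measurement noise is a 0.003 mole-fraction standard uncertainty,
typical of titration/chromatography phase analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .components import ComponentSet
from .estimation import TieLineDataset
from .flash import TieLine, binodal_curve
from .nrtl import NrtlParameterSet, stability_test

__all__ = [
    "PRESETS",
    "make_demixing_system",
    "generate_tielines",
    "SyntheticTieLines",
]

#: measured-data-like standard uncertainty in mole fraction
DEFAULT_NOISE_SD = 0.003

PRESETS = (
    "binary_symmetric",
    "ternary_type1",
    "ternary_broth_like",
    "quaternary_broth_like",
)

_BINARY = ComponentSet(("water", "ester"), (18.015, 172.26))
_TERNARY = ComponentSet(("water", "solute", "ester"), (18.015, 88.11, 172.26))
_QUATERNARY = ComponentSet(
    ("water", "acetic acid", "butyric acid", "octyl acetate"),
    (18.015, 60.052, 88.11, 172.26),
)


def make_demixing_system(
    kind: str, seed: int = 0, jitter: float = 0.0
) -> tuple[ComponentSet, NrtlParameterSet]:
    """A component set and NRTL parameters whose binodal exists.

    Presets
    -------
    binary_symmetric
        Two components with tau12 = tau21, alpha = 0.2: a symmetric
        miscibility gap centered at x = 0.5.
    ternary_type1
        Water/solute/ester with exactly one immiscible binary edge
        (water-ester); the solute is miscible with both.
    ternary_broth_like
        As type 1 but with a wide water-ester gap and a solute that
        partitions preferentially into the ester phase (D > 1), mimicking a
        fermentation acid extracted by a high-boiling ester.
    quaternary_broth_like
        Water/acetic acid/butyric acid/ester stand-in for the full broth
        extraction, with a strongly partitioned C4 acid and a weakly
        partitioned C2 side product.

    ``jitter`` adds seeded Gaussian perturbations (sd = jitter) to the free
    tau entries, preserving preset symmetries, so property tests can sample
    many distinct demixing systems; jitter = 0 returns the canonical preset.
    """
    rng = np.random.default_rng(seed)
    if kind == "binary_symmetric":
        comps = _BINARY
        t = 3.0 + jitter * rng.normal()
        tau = np.array([[0.0, t], [t, 0.0]])
        alpha = np.array([[0.0, 0.2], [0.2, 0.0]])
    elif kind == "ternary_type1":
        comps = _TERNARY
        tau = np.array(
            [
                [0.0, 0.8, 3.2],
                [0.4, 0.0, 0.3],
                [2.6, 0.2, 0.0],
            ]
        )
        alpha = np.full((3, 3), 0.2)
        np.fill_diagonal(alpha, 0.0)
    elif kind == "ternary_broth_like":
        comps = _TERNARY
        # water-ester strongly immiscible; solute dislikes water, likes ester
        tau = np.array(
            [
                [0.0, 1.0, 4.2],
                [0.3, 0.0, -0.3],
                [3.1, -0.2, 0.0],
            ]
        )
        alpha = np.full((3, 3), 0.2)
        np.fill_diagonal(alpha, 0.0)
    elif kind == "quaternary_broth_like":
        # synthetic stand-in for a broth/ester extraction system with the
        # acetic-acid side product: one immiscible edge (water-ester), the
        # acids miscible with water but strongly favoring the ester phase
        comps = _QUATERNARY
        tau = np.array(
            [
                [0.0, 0.6, 1.2, 4.2],
                [0.2, 0.0, 0.1, 0.8],
                [0.8, 0.1, 0.0, -1.5],
                [3.1, 0.6, -1.0, 0.0],
            ]
        )
        alpha = np.full((4, 4), 0.2)
        np.fill_diagonal(alpha, 0.0)
    else:
        raise ValueError(f"unknown preset {kind!r}; choose from {PRESETS}")
    if jitter > 0 and comps.n == 3:
        pert = jitter * rng.normal(size=(3, 3))
        np.fill_diagonal(pert, 0.0)
        tau = tau + pert
    params = NrtlParameterSet(components=comps, tau=tau, alpha=alpha)
    # sanity: the water/ester edge must demix
    edge = np.zeros(comps.n)
    edge[0] = 0.5
    edge[-1] = 0.5
    if stability_test(edge, params.T_ref, params).stable:
        raise RuntimeError(
            f"preset {kind!r} (seed={seed}, jitter={jitter}) lost its "
            "miscibility gap"
        )
    return comps, params


@dataclass(frozen=True)
class SyntheticTieLines:
    """Noisy dataset plus the noiseless truth it was generated from."""

    data: TieLineDataset
    truth: TieLineDataset
    params: NrtlParameterSet


def generate_tielines(
    system: tuple[ComponentSet, NrtlParameterSet],
    n: int,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    T: Optional[float] = None,
    extent: float = 0.7,
) -> SyntheticTieLines:
    """n noisy tie-lines from a ground-truth system.

    Tie-lines are selected evenly over the first ``extent`` fraction of the
    traced binodal (:func:`binodal_curve`), emulating measured LLE tables:
    experiments report tie-lines with clearly distinct phases and stop well
    short of the plait point, where phase analysis becomes impossible and
    a fixed composition uncertainty would swamp the signal. Each phase
    composition is perturbed by independent Gaussian noise of standard
    deviation ``noise_sd``, clipped to [0, 1] and renormalized to the
    simplex. The noiseless truth is returned alongside for
    parameter-recovery tests.
    """
    if n < 2:
        raise ValueError("need at least 2 tie-lines")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if not 0 < extent <= 1:
        raise ValueError("extent must be in (0, 1]")
    comps, params = system
    T = params.T_ref if T is None else T
    full = binodal_curve(T, params, n_lines=0)
    usable = full[: max(n, int(round(extent * len(full))))]
    if len(usable) < n:
        raise RuntimeError(
            f"system yields only {len(usable)} tie-lines in the sampled range"
        )
    pick = np.unique(np.round(np.linspace(0, len(usable) - 1, n)).astype(int))
    clean = [usable[i] for i in pick]
    rng = np.random.default_rng(seed)

    def perturb(x: np.ndarray) -> np.ndarray:
        if noise_sd == 0:
            return x.copy()
        y = np.clip(x + rng.normal(0.0, noise_sd, size=x.shape), 0.0, 1.0)
        return y / y.sum()

    noisy = []
    for tl in clean:
        noisy.append(TieLine(x_org=perturb(tl.x_org), x_aq=perturb(tl.x_aq), T=T))
    return SyntheticTieLines(
        data=TieLineDataset(comps, tuple(noisy), T=T, noise_sd=noise_sd),
        truth=TieLineDataset(comps, tuple(clean), T=T, noise_sd=0.0),
        params=params,
    )
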