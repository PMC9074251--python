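"""Steady-state countercurrent multistage equilibrium extraction.

Stages are numbered from the top: the aqueous feed enters stage 1 and flows
downward, the solvent enters stage N and the organic phase flows upward.
Each stage equilibrates its combined inlet with an isothermal two-liquid
flash; the extract is the organic stream leaving stage 1 and the raffinate
(wastewater) the aqueous stream leaving stage N. The cascade is solved by
repeated stage sweeps (successive substitution on the interstage streams).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .components import ComponentSet
from .flash import TieLine, lle_flash
from .nrtl import NrtlParameterSet

__all__ = [
    "Stream",
    "CascadeResult",
    "simulate_extractor",
    "recovery",
    "distribution_and_selectivity",
    "lever_material_balance",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Stream:
    """Named-component molar flows (kmol/h)."""

    components: ComponentSet
    component_flows: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.component_flows, dtype=float)
        if f.shape != (self.components.n,):
            raise ValueError("component_flows length must match components")
        if np.any(f < 0):
            raise ValueError(f"negative component flow in stream {self.label!r}")
        f = f.copy()
        f.setflags(write=False)
        object.__setattr__(self, "component_flows", f)

    @property
    def total(self) -> float:
        """Total molar flow, kmol/h."""
        return float(self.component_flows.sum())

    @property
    def x(self) -> np.ndarray:
        """Mole fractions."""
        if self.total == 0:
            raise ValueError(f"stream {self.label!r} has zero flow")
        return self.component_flows / self.total

    def flow_of(self, name: str) -> float:
        return float(self.component_flows[self.components.index(name)])

    def mass_flows(self) -> np.ndarray:
        """Per-component mass flows, kg/h."""
        return self.component_flows * self.components.masses()

    @classmethod
    def from_composition(
        cls,
        components: ComponentSet,
        total_flow: float,
        x: Sequence[float],
        label: str = "",
    ) -> "Stream":
        x = np.asarray(x, float)
        return cls(components, total_flow * x / x.sum(), label)

    def scaled(self, factor: float) -> "Stream":
        return Stream(self.components, self.component_flows * factor, self.label)

    def __add__(self, other: "Stream") -> "Stream":
        if self.components.names != other.components.names:
            raise ValueError("cannot add streams over different component sets")
        return Stream(self.components, self.component_flows + other.component_flows)


@dataclass(frozen=True)
class CascadeResult:
    extract: Stream
    raffinate: Stream
    #: per stage: (x_aqueous, x_organic, aqueous flow out, organic flow out)
    stage_profiles: tuple[tuple[np.ndarray, np.ndarray, float, float], ...]
    converged: bool
    iterations: int
    balance_residual: float  # max relative component imbalance, inlets vs outlets


def simulate_extractor(
    feed: Stream,
    solvent: Stream,
    n_stages: int,
    T: float,
    params: NrtlParameterSet,
    tol: float = 1e-9,
    max_sweeps: int = 500,
) -> CascadeResult:
    """Simulate an N-stage countercurrent extractor at temperature T.

    Sweeps stages top to bottom, flashing each stage's combined inlet
    (aqueous from above + organic from below) and updating the interstage
    streams until the relative stage-to-stage change falls below ``tol``.
    A stage whose combined inlet is single-phase passes it through to the
    phase its composition resembles, with a warning.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    comps = feed.components
    if comps.names != solvent.components.names:
        raise ValueError("feed and solvent must share a component set")
    if params.n != comps.n:
        raise ValueError("parameter set does not cover the stream components")
    n = comps.n

    # organic upflow entering each stage from below; index j is the organic
    # stream entering stage j (leaving stage j+1); entry n_stages-1 <- solvent
    org_in = [solvent.component_flows.copy() for _ in range(n_stages)]
    aq_out = [feed.component_flows.copy() for _ in range(n_stages)]
    org_out = [solvent.component_flows.copy() for _ in range(n_stages)]

    converged = False
    sweep = 0
    trials: list[Optional[np.ndarray]] = [None] * n_stages  # warm starts
    for sweep in range(1, max_sweeps + 1):
        max_change = 0.0
        aq_above = feed.component_flows
        for j in range(n_stages):
            inlet = aq_above + org_in[j]
            total = inlet.sum()
            z = inlet / total
            try:
                fr = lle_flash(z, T, params, init=trials[j])
            except RuntimeError:
                fr = lle_flash(z, T, params)  # cold restart with stability test
            trials[j] = fr.x_II if fr.two_phase else None
            if fr.two_phase and fr.converged:
                new_org = total * fr.L_II * fr.x_II
                new_aq = total * (1.0 - fr.L_II) * fr.x_I
            else:
                # single-phase stage: pass through to the like phase
                logger.warning(
                    "stage %d inlet is single-phase; passing through", j + 1
                )
                if z[0] >= z[-1]:  # water-rich -> aqueous
                    new_aq, new_org = inlet, np.zeros(n)
                else:
                    new_aq, new_org = np.zeros(n), inlet
            scale = max(total, 1e-300)
            max_change = max(
                max_change,
                float(np.max(np.abs(new_aq - aq_out[j])) / scale),
                float(np.max(np.abs(new_org - org_out[j])) / scale),
            )
            aq_out[j] = new_aq
            org_out[j] = new_org
            aq_above = new_aq
        # propagate organic streams upward for the next sweep
        for j in range(n_stages - 1):
            org_in[j] = org_out[j + 1]
        org_in[n_stages - 1] = solvent.component_flows
        inlets = feed.component_flows + solvent.component_flows
        outlets = org_out[0] + aq_out[n_stages - 1]
        balance = float(
            np.max(np.abs(inlets - outlets) / np.maximum(inlets, 1e-300))
        )
        # closure lags the stage sweep by one update, so require both
        if max_change < tol and balance < max(10.0 * tol, 1e-9):
            converged = True
            break
    if not converged:
        logger.warning("cascade failed to converge in %d sweeps", max_sweeps)

    extract = Stream(comps, org_out[0], label="extract")
    raffinate = Stream(comps, aq_out[n_stages - 1], label="raffinate")
    profiles = tuple(
        (
            aq_out[j] / s if (s := aq_out[j].sum()) > 0 else aq_out[j],
            org_out[j] / t if (t := org_out[j].sum()) > 0 else org_out[j],
            float(aq_out[j].sum()),
            float(org_out[j].sum()),
        )
        for j in range(n_stages)
    )
    return CascadeResult(
        extract=extract,
        raffinate=raffinate,
        stage_profiles=profiles,
        converged=converged,
        iterations=sweep,
        balance_residual=balance,
    )


def recovery(feed: Stream, outlet: Stream, component: str) -> float:
    """Fraction of a feed component leaving in the outlet stream."""
    fin = feed.flow_of(component)
    if fin <= 0:
        raise ValueError(f"feed contains no {component!r}")
    return outlet.flow_of(component) / fin


def distribution_and_selectivity(
    tieline: TieLine,
    solute: str | int,
    reference: str | int,
    components: Optional[ComponentSet] = None,
) -> tuple[float, float]:
    """Distribution coefficient D and selectivity S of a solute.

    D = x_solute,org / x_solute,aq;  S = D_solute / D_reference (reference
    is conventionally water). D is +inf (with a log flag) when the solute is
    absent from the aqueous phase.
    """

    def _idx(c) -> int:
        if isinstance(c, int):
            return c
        if components is None:
            raise ValueError("component names require a ComponentSet")
        return components.index(c)

    i, r = _idx(solute), _idx(reference)
    if tieline.x_aq[i] == 0:
        logger.warning("solute absent from aqueous phase; D = +inf")
        return math.inf, math.inf
    D = tieline.x_org[i] / tieline.x_aq[i]
    D_ref = tieline.x_org[r] / tieline.x_aq[r]
    return float(D), float(D / D_ref)


def lever_material_balance(
    feed: Stream, solvent: Stream
) -> tuple[np.ndarray, float, float]:
    """Mixing point M of feed and solvent and the lever-rule ratio.

    Returns (x_M, d(S,M)/d(M,F), feed/solvent molar flow ratio); the two
    ratios agree because M is the flow-weighted mean composition.
    """
    if feed.total <= 0 or solvent.total <= 0:
        raise ValueError("both streams must have positive flow")
    mixed = feed + solvent
    x_M = mixed.x
    flow_ratio = feed.total / solvent.total
    d_SM = float(np.linalg.norm(solvent.x - x_M))
    d_MF = float(np.linalg.norm(x_M - feed.x))
    if d_MF < 1e-12:  # degenerate: identical compositions
        return x_M, flow_ratio, flow_ratio
    return x_M, d_SM / d_MF, flow_ratio
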