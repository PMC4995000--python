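"""Steady-state selection and bifurcation analysis of commitment.

The committed T-cell state has TCF-1, GATA-3 and BCL11B high and PU.1
low.  Whether commitment is *irreversible* is probed by continuing the
committed steady state while the maximum Notch signal is scaled down
from its full value to zero (natural-parameter continuation by
relaxation): if the BCL11B branch still sits within 50% of its
committed value at zero Notch, the configuration locks the fate in;
if it collapses to the low branch, commitment is reversible.  Because
PU.1 has no regulated positive inputs, P = 0 is an invariant manifold
and PU.1 can never reactivate once silenced (unless a constant external
drive such as RUNX1 is switched on).

Coexisting steady states (the unstable separatrix between low and high
branches) are charted by multi-start root finding inside the box
[0, f_X/gamma_X] per gene, with stability read off the Jacobian
eigenvalues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import root

from .model import (
    GENES,
    GeneState,
    ModelSpec,
    SimulationError,
    _jacobian,
    rhs,
    simulate,
    steady_state,
)
from .calibration import Pu1Params

__all__ = [
    "BifurcationDiagram",
    "bifurcation_scan",
    "classify_commitment",
    "select_steady_sets",
    "find_steady_states",
]


# ---------------------------------------------------------------------------
# Multi-start steady-state search
# ---------------------------------------------------------------------------


def find_steady_states(
    spec: ModelSpec,
    nu: float,
    clamps: Optional[Mapping[str, float]] = None,
    n_starts: int = 20,
    seed: int = 0,
    include: Sequence[GeneState] = (),
) -> List[Tuple[GeneState, bool]]:
    """All distinct steady states found by multi-start root finding.

    Random starts are drawn uniformly in the box [0, f_X/gamma_X] per
    free gene; converged roots are deduplicated at 1e-6 relative (on the
    ceiling scale) and labelled stable/unstable by Jacobian eigenvalues.
    """
    clamps = dict(clamps or {})
    clamp_fixed = {GENES.index(g): float(v) for g, v in clamps.items()}
    free = [i for i in range(4) if i not in clamp_fixed]
    ceilings = np.array([
        max(spec.params.ceiling(GENES[i]), 1e-300) if spec.params.f[i] > 0 else 1.0
        for i in range(4)
    ])
    rng = np.random.default_rng(seed)

    def resid(uf: np.ndarray) -> np.ndarray:
        full = np.empty(4)
        for k, i in enumerate(free):
            full[i] = max(uf[k], 0.0) * ceilings[i]
        for i, v in clamp_fixed.items():
            full[i] = v
        dx = rhs(full, 0.0, spec, nu=nu)
        return np.array([
            dx[i] / (spec.params.f[i] if spec.params.f[i] > 0 else 1.0) for i in free
        ])

    starts = [np.asarray(s, dtype=float)[free] / ceilings[free] for s in include]
    starts += [rng.uniform(0.0, 1.0, size=len(free)) for _ in range(n_starts)]

    found: List[Tuple[GeneState, bool]] = []
    found_scaled: List[np.ndarray] = []
    for u0 in starts:
        sol = root(resid, u0, method="hybr", tol=1e-13)
        if not sol.success or np.max(np.abs(sol.fun)) > 1e-9:
            continue
        u = np.clip(sol.x, 0.0, None)
        if any(np.allclose(u, v, rtol=0, atol=1e-6) for v in found_scaled):
            continue
        full = np.empty(4)
        for k, i in enumerate(free):
            full[i] = u[k] * ceilings[i]
        for i, v in clamp_fixed.items():
            full[i] = v
        jac = _jacobian(full, spec, nu, clamp_fixed)
        stable = bool(np.max(np.linalg.eigvals(jac).real) < 0)
        found_scaled.append(u)
        found.append((GeneState(*full), stable))
    return found


# ---------------------------------------------------------------------------
# Bifurcation diagram
# ---------------------------------------------------------------------------


@dataclass
class BifurcationDiagram:
    """Steady-state branches against the Notch scale factor s in [0, 1]."""

    config_id: str
    s_grid: np.ndarray
    branch: np.ndarray  # shape (4, n_points): swept (followed) branch
    stable: np.ndarray  # shape (n_points,), bool
    direction: str  # "down" or "up"
    extra_states: List[List[Tuple[GeneState, bool]]] = field(default_factory=list)
    clamps: Dict[str, float] = field(default_factory=dict)

    def gene_branch(self, gene: str) -> np.ndarray:
        return self.branch[GENES.index(gene)]

    @property
    def committed_state(self) -> GeneState:
        """The branch state at full Notch (s = 1)."""
        idx = int(np.argmax(self.s_grid)) if self.direction == "up" else 0
        return GeneState(*self.branch[:, idx])

    def value_at(self, gene: str, s: float) -> float:
        idx = int(np.argmin(np.abs(self.s_grid - s)))
        return float(self.branch[GENES.index(gene), idx])

    def to_frame(self):
        """Tidy frame: s, gene, branch_id, value, stable."""
        import pandas as pd

        rows = []
        for j, s in enumerate(self.s_grid):
            for i, g in enumerate(GENES):
                rows.append((float(s), g, 0, float(self.branch[i, j]), bool(self.stable[j])))
            if self.extra_states:
                for b_id, (state, stab) in enumerate(self.extra_states[j], start=1):
                    for i, g in enumerate(GENES):
                        rows.append((float(s), g, b_id, float(state[i]), bool(stab)))
        return pd.DataFrame(rows, columns=["s", "gene", "branch_id", "value", "stable"])

    def plot(self, ax=None, genes: Sequence[str] = GENES):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"T": "tab:blue", "G": "tab:red", "B": "m", "P": "tab:green"}
        for g in genes:
            ax.plot(self.s_grid, self.gene_branch(g), color=colors[g], label=g)
        ax.set_xlabel("Notch scale factor s")
        ax.set_ylabel("steady expression")
        ax.legend()
        return ax


def bifurcation_scan(
    spec: ModelSpec,
    start_state: GeneState,
    direction: str = "down",
    n_points: int = 101,
    clamps: Optional[Mapping[str, float]] = None,
    n_multistart: int = 20,
    seed: int = 0,
    chart_extra: bool = True,
) -> BifurcationDiagram:
    """Continue steady states across the Notch scale factor s in [0, 1].

    Simulation-based natural-parameter continuation: at each s along the
    sweep the system is relaxed to steady state starting from the
    previous point's state.  When ``chart_extra`` is set, coexisting
    steady states at each s are charted with ``n_multistart`` random
    root-finding starts to expose unstable/other branches.
    """
    if n_points < 10:
        raise ValueError("n_points must be at least 10")
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    s_grid = np.linspace(1.0, 0.0, n_points) if direction == "down" else np.linspace(0.0, 1.0, n_points)

    clamps = dict(clamps or {})
    branch = np.empty((4, n_points))
    stable_flags = np.empty(n_points, dtype=bool)
    extra: List[List[Tuple[GeneState, bool]]] = []

    state = GeneState(*start_state)
    for j, s in enumerate(s_grid):
        state, stable = steady_state(
            spec, float(s) * spec.notch.n_max, state, clamps=clamps
        )
        branch[:, j] = np.asarray(state)
        stable_flags[j] = stable
        if chart_extra and n_multistart > 0:
            extra.append(
                find_steady_states(
                    spec, float(s), clamps=clamps, n_starts=n_multistart,
                    seed=seed + j, include=[state],
                )
            )
        else:
            extra.append([])
    return BifurcationDiagram(
        config_id=spec.logic.variant_id,
        s_grid=s_grid,
        branch=branch,
        stable=stable_flags,
        direction=direction,
        extra_states=extra,
        clamps=dict(clamps),
    )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

_IRREVERSIBLE_FRACTION = 0.5
_BISTABLE_REL_TOL = 0.05
_OFF_ATOL_FRACTION = 1e-9  # of the gene ceiling


def classify_gene(
    diagram_down: BifurcationDiagram,
    diagram_up: Optional[BifurcationDiagram],
    gene: str,
    irreversible_fraction: float = _IRREVERSIBLE_FRACTION,
) -> str:
    down = diagram_down.gene_branch(gene)
    committed = float(down[0])
    final = float(down[-1])
    try:
        ceiling = diagram_down_ceiling = max(
            abs(committed), abs(down).max(), 1e-300
        )
    except ValueError:
        ceiling = 1e-300
    off_tol = _OFF_ATOL_FRACTION * max(ceiling, 1.0)

    if committed <= off_tol:
        return "irreversible-off" if np.all(down <= off_tol) else "reactivated"
    if final >= irreversible_fraction * committed:
        return "irreversible"
    # the branch collapsed; distinguish a genuine hysteretic drop from a
    # smooth monostable decline
    rel_steps = np.abs(np.diff(down)) / max(abs(committed), 1e-300)
    has_jump = bool(np.any(rel_steps > 0.5))
    bistable = False
    if diagram_up is not None:
        up = diagram_up.gene_branch(gene)
        up_aligned = up[::-1] if diagram_up.direction != diagram_down.direction else up
        denom = np.maximum(np.maximum(np.abs(down), np.abs(up_aligned)), 1e-300)
        bistable = bool(np.any(np.abs(down - up_aligned) / denom > _BISTABLE_REL_TOL))
    if has_jump or bistable:
        return "reversible"
    return "monostable"


def classify_commitment(
    diagram_down: BifurcationDiagram,
    diagram_up: Optional[BifurcationDiagram] = None,
    irreversible_fraction: float = _IRREVERSIBLE_FRACTION,
) -> Dict[str, str]:
    """Per-gene commitment classification from sweep diagrams.

    A gene is *irreversible* when the downward branch at zero Notch
    stays within ``irreversible_fraction`` (default 50%) of its
    committed value; *reversible* when it collapses to the low branch
    (hysteretic jump or disagreement with the upward sweep); and
    *monostable* when the branch declines smoothly with no bistable
    region.  A gene whose committed value is already zero (PU.1 with no
    external drive) is *irreversible-off*.
    """
    if diagram_up is not None and len(diagram_up.s_grid) != len(diagram_down.s_grid):
        raise ValueError("sweeps must share the same grid resolution")
    out = {}
    for g in GENES:
        if g in diagram_down.clamps:
            v = diagram_down.clamps[g]
            out[g] = "clamped-off" if v == 0 else "clamped"
            continue
        out[g] = classify_gene(diagram_down, diagram_up, g, irreversible_fraction)
    return out


def bistable_region(
    diagram_down: BifurcationDiagram,
    diagram_up: BifurcationDiagram,
    gene: str,
    rel_tol: float = _BISTABLE_REL_TOL,
) -> List[float]:
    """Grid values of s where the two sweeps disagree by > rel_tol."""
    down = diagram_down.gene_branch(gene)
    up = diagram_up.gene_branch(gene)
    if diagram_up.direction != diagram_down.direction:
        up = up[::-1]
    denom = np.maximum(np.maximum(np.abs(down), np.abs(up)), 1e-300)
    mask = np.abs(down - up) / denom > rel_tol
    return [float(s) for s in diagram_down.s_grid[mask]]


# ---------------------------------------------------------------------------
# Full-network steady-state selection
# ---------------------------------------------------------------------------


def select_steady_sets(
    spec: ModelSpec,
    pu1_sets: Sequence[Pu1Params],
    reference: Mapping[str, float],
    high_frac: float = 0.5,
    low_frac: float = 0.1,
    init: Optional[GeneState] = None,
) -> List[Pu1Params]:
    """Keep PU.1 parameter sets that reach a committed full-network steady state.

    For each candidate set the full four-gene system (best TGB
    parameters fixed) is integrated from a day-0-like state at full
    Notch until steady; the set is accepted when TCF-1, GATA-3 and
    BCL11B all reach at least ``high_frac`` of their reference day-4
    values while PU.1 falls to at most ``low_frac`` of its day-0 value.
    ``reference`` must carry keys ``T4``, ``G4``, ``B4`` and ``P0``.
    """
    for key in ("T4", "G4", "B4", "P0"):
        if key not in reference:
            raise ValueError(f"reference must contain {key!r}")
    accepted = []
    for pu1 in pu1_sets:
        full = replace(spec, params=pu1.apply(spec.params))
        start = init if init is not None else GeneState(
            0.02 * full.params.ceiling("T"),
            0.02 * full.params.ceiling("G"),
            0.02 * full.params.ceiling("B"),
            reference["P0"],
        )
        try:
            state, _ = steady_state(full, full.notch.n_max, start)
        except SimulationError:
            continue
        ok = (
            state.T >= high_frac * reference["T4"]
            and state.G >= high_frac * reference["G4"]
            and state.B >= high_frac * reference["B4"]
            and state.P <= low_frac * reference["P0"]
        )
        if ok:
            accepted.append(pu1)
    return accepted
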