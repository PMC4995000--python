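"""Model/Results interface tying the pipeline together.

``CommitmentModel`` holds a five-stage expression dataset and one
combinatorial configuration for BCL11B regulation; ``fit`` runs the
constrained two-leg estimation (TGB subsystem with PU.1 clamped, then
optionally the PU.1 ensemble) and returns a ``CommitmentResults``
carrying the estimates, the filter verdicts and the diagnostic
summaries, with simulation and bifurcation analysis hanging off it.

    >>> data = generate_reference_dataset(seed=1)
    >>> model = CommitmentModel(data.series, logic="6d")
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .calibration import (
    DEFAULT_FOLD_CAP,
    DEFAULT_HL_WINDOW,
    FitResult,
    InfeasibilityError,
    ParameterBounds,
    Pu1Params,
    default_bounds,
    derive_notch_bounds,
    derive_pu1_bounds,
    filter_fits,
    fit_pu1,
    fit_tgb,
    series_map,
)
from .commitment import (
    BifurcationDiagram,
    bifurcation_scan,
    classify_commitment,
    select_steady_sets,
)
from .logic import LogicConfig, get_configuration
from .model import GENES, GeneState, ModelSpec, steady_state
from .staging import ExpressionSeries, smooth_series

__all__ = ["CommitmentModel", "CommitmentResults", "fitresult_to_dict", "fitresult_from_dict"]


class CommitmentModel:
    """A commitment model: one logic configuration fitted to stage data.

    Parameters
    ----------
    data : mapping or sequence of ExpressionSeries
        Five-stage series for TCF-1, GATA-3, BCL11B and PU.1.
    logic : str or LogicConfig
        Combinatorial configuration for BCL11B regulation (e.g. "6d").
    cv : float
        Coefficient of variation assumed for the data (default 0.25).
    fold_cap : float
        Maximum allowed Notch fold increase between day 0 and 4.
    hl_window : (float, float)
        Plausible protein half-life window in hours.
    """

    def __init__(
        self,
        data: Union[Mapping[str, ExpressionSeries], Sequence[ExpressionSeries]],
        logic: Union[str, LogicConfig] = "6d",
        cv: float = 0.25,
        fold_cap: float = DEFAULT_FOLD_CAP,
        hl_window: Tuple[float, float] = DEFAULT_HL_WINDOW,
    ):
        self.data = series_map(data)
        missing = [g for g in "TGBP" if g not in self.data]
        if missing:
            raise ValueError(f"data is missing genes: {missing}")
        self.logic = logic if isinstance(logic, LogicConfig) else get_configuration(logic)
        self.cv = cv
        self.fold_cap = fold_cap
        self.hl_window = hl_window

    @classmethod
    def from_dataframe(cls, frame, cv: float = 0.25, **kwargs) -> "CommitmentModel":
        """Build from a tidy stage,gene,value DataFrame."""
        from .staging import stage_to_time

        series = []
        for gene, grp in frame.groupby("gene", sort=False):
            days = grp["stage"].map(stage_to_time).to_numpy()
            order = np.argsort(days)
            series.append(
                ExpressionSeries(
                    gene=str(gene), times=days[order],
                    values=grp["value"].to_numpy()[order], cv=cv,
                )
            )
        return cls(series, cv=cv, **kwargs)

    def smooth_profiles(self):
        return {g: smooth_series(s) for g, s in self.data.items()}

    def derive_bounds(self, seed: int = 0, n_samples: int = 4000) -> ParameterBounds:
        return derive_notch_bounds(
            self.smooth_profiles(), self.logic, fold_cap=self.fold_cap,
            n_samples=n_samples, seed=seed, cv=self.cv, hl_window=self.hl_window,
        )

    def fit(
        self,
        seed: int = 0,
        bounds: Optional[ParameterBounds] = None,
        maxiter: int = 120,
        with_pu1: bool = False,
        pu1_starts: int = 10,
        pu1_maxiter: int = 80,
        hl_mode: str = "effective",
    ) -> "CommitmentResults":
        """Run the two-leg estimation and filtering; deterministic per seed."""
        if bounds is None:
            try:
                bounds = self.derive_bounds(seed=seed)
            except InfeasibilityError:
                # noisy data can leave the sampled feasible set empty; fall
                # back to broad data-scaled bounds (the fold cap still holds
                # by construction of the signal parameterisation)
                bounds = default_bounds(
                    self.data, self.logic, fold_cap=self.fold_cap,
                    hl_window=self.hl_window,
                )
        fit = fit_tgb(self.logic, self.data, bounds, seed=seed, maxiter=maxiter)
        filter_fits(
            [fit], self.data, cv=self.cv, hl_window=self.hl_window, hl_mode=hl_mode
        )
        pu1_sets: List[Pu1Params] = []
        if with_pu1:
            profiles = self.smooth_profiles()
            pu1_bounds = derive_pu1_bounds(profiles, n_mc=200, seed=seed)
            pu1_sets = fit_pu1(
                self.data, pu1_bounds, n_starts=pu1_starts, seed=seed,
                maxiter=pu1_maxiter, cv=self.cv,
            )
        return CommitmentResults(model=self, fit=fit, pu1_sets=pu1_sets)


@dataclass
class CommitmentResults:
    """Estimates, filter verdicts and analyses for one fitted configuration."""

    model: CommitmentModel
    fit: FitResult
    pu1_sets: List[Pu1Params] = field(default_factory=list)

    # -- convenience accessors -------------------------------------------
    @property
    def params(self):
        return self.fit.params

    @property
    def notch(self):
        return self.fit.notch

    @property
    def objective(self) -> Dict[str, float]:
        return self.fit.objective

    @property
    def accepted(self) -> bool:
        return self.fit.accepted

    @property
    def half_lives(self) -> Dict[str, float]:
        return self.fit.half_lives

    def spec(self, pu1: Optional[Pu1Params] = None) -> ModelSpec:
        spec = self.fit.spec()
        if pu1 is not None:
            from dataclasses import replace

            spec = replace(spec, params=pu1.apply(spec.params))
        return spec

    # -- analyses ---------------------------------------------------------
    def simulate(self, t_grid=None, pu1: Optional[Pu1Params] = None, **kwargs):
        spec = self.spec(pu1)
        if t_grid is None:
            t_grid = np.linspace(0.0, 4.0, 81)
        sm = self.model.data
        if pu1 is None:
            profile = self.fit.diagnostics.get("p_profile")
            clamps = {"P": (lambda t: float(profile.value(t)))} if profile else None
            init = GeneState(
                sm["T"].values[0], sm["G"].values[0], sm["B"].values[0],
                float(profile.value(0.0)) if profile else sm["P"].values[0],
            )
            return simulate_with(spec, init, t_grid, clamps, **kwargs)
        init = GeneState(
            sm["T"].values[0], sm["G"].values[0], sm["B"].values[0], sm["P"].values[0]
        )
        return simulate_with(spec, init, t_grid, None, **kwargs)

    def bifurcation(
        self,
        clamp_pu1: bool = True,
        pu1: Optional[Pu1Params] = None,
        n_points: int = 101,
        chart_extra: bool = False,
        seed: int = 0,
    ) -> Tuple[BifurcationDiagram, BifurcationDiagram, Dict[str, str]]:
        """Down- and up-sweep diagrams plus per-gene classification."""
        spec = self.spec(pu1)
        clamps = {"P": 0.0} if clamp_pu1 and pu1 is None else None
        ceilings = spec.ceilings()
        committed, _ = steady_state(
            spec,
            spec.notch.n_max,
            GeneState(0.9 * ceilings["T"], 0.9 * ceilings["G"], 0.9 * ceilings["B"], 0.0),
            clamps=clamps,
        )
        down = bifurcation_scan(
            spec, committed, "down", n_points=n_points, clamps=clamps,
            chart_extra=chart_extra, seed=seed,
        )
        low = GeneState(1e-6 * ceilings["T"], 1e-6 * ceilings["G"], 1e-6 * ceilings["B"], 0.0)
        up = bifurcation_scan(
            spec, low, "up", n_points=n_points, clamps=clamps,
            chart_extra=chart_extra, seed=seed,
        )
        return down, up, classify_commitment(down, up)

    def select_pu1_sets(self, high_frac: float = 0.5, low_frac: float = 0.1):
        sm = self.model.data
        reference = {
            "T4": float(sm["T"].values[-1]),
            "G4": float(sm["G"].values[-1]),
            "B4": float(sm["B"].values[-1]),
            "P0": float(sm["P"].values[0]),
        }
        return select_steady_sets(
            self.fit.spec(), self.pu1_sets, reference,
            high_frac=high_frac, low_frac=low_frac,
        )

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        fit = self.fit
        lines = []
        lines.append("          T-cell commitment model fit")
        lines.append("=" * 58)
        lines.append(f"configuration: {fit.config.variant_id}   {fit.config.describe()}")
        lines.append(
            f"genes fitted: TCF-1, GATA-3, BCL11B (PU.1 clamped); "
            f"n obs = {3 * len(self.model.data['T'].times)}"
        )
        lines.append(
            f"objective (normalised SSR): "
            + ", ".join(f"{g}={v:.4g}" for g, v in fit.objective.items())
            + f"   total={fit.total_objective:.4g}"
        )
        lines.append(f"Notch fold increase day0->day4: {fit.notch_fold:.3f} (cap {self.model.fold_cap})")
        lines.append("-" * 58)
        lines.append(f"{'parameter':<12}{'estimate':>14}")
        theta = fit.diagnostics.get("theta", {})
        for name, value in theta.items():
            lines.append(f"{name:<12}{value:>14.5g}")
        lines.append("-" * 58)
        if fit.half_lives:
            lines.append(
                "effective half-lives (h): "
                + ", ".join(f"{g}={h:.2f}" for g, h in fit.half_lives.items())
            )
        if fit.ci_pass:
            lines.append(
                "95% CI filter: "
                + ", ".join(f"{g}={'pass' if ok else 'FAIL'}" for g, ok in fit.ci_pass.items())
            )
        lines.append(f"accepted: {fit.accepted}")
        if self.pu1_sets:
            lines.append(f"PU.1 ensemble: {len(self.pu1_sets)} parameter sets")
        lines.append("=" * 58)
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"T": "tab:blue", "G": "tab:red", "B": "m", "P": "tab:green"}
        traj = self.fit.diagnostics.get("trajectory")
        sm = self.model.data
        for g in "TGB":
            s = sm[g]
            lo, hi = s.confidence_band()
            ax.errorbar(s.times, s.values, yerr=[s.values - lo, hi - s.values],
                        fmt="o", color=colors[g], label=f"{s.gene} data")
            if traj is not None:
                ax.plot(traj.times, traj[g], color=colors[g])
        ax.set_xlabel("time (days)")
        ax.set_ylabel("expression (a.u.)")
        ax.legend()
        return ax


def simulate_with(spec, init, t_grid, clamps, **kwargs):
    from .model import simulate

    return simulate(spec, init, t_grid, clamps=clamps, **kwargs)


# ---------------------------------------------------------------------------
# Fit (de)serialization for reports and the CLI
# ---------------------------------------------------------------------------


def fitresult_to_dict(fit: FitResult) -> Dict:
    return {
        "config": fit.config.variant_id,
        "gate": fit.config.gate,
        "theta": fit.diagnostics.get("theta", {}),
        "objective": fit.objective,
        "notch_fold": fit.notch_fold,
        "ci_pass": fit.ci_pass,
        "half_lives": {g: (None if np.isinf(h) else h) for g, h in fit.half_lives.items()},
        "accepted": fit.accepted,
        "seed": fit.diagnostics.get("seed"),
    }


def fitresult_from_dict(d: Mapping) -> FitResult:
    from .calibration import _build_spec  # shared construction path
    from .logic import compile_rate_law

    config = get_configuration(d["config"])
    rate_law = compile_rate_law(config)
    spec = _build_spec(d["theta"], config, rate_law)
    return FitResult(
        config=config,
        params=spec.params,
        notch=spec.notch,
        objective=dict(d.get("objective", {})),
        notch_fold=float(d.get("notch_fold", spec.notch.fold())),
        ci_pass=dict(d.get("ci_pass", {})),
        half_lives={g: (float("inf") if h is None else h)
                    for g, h in d.get("half_lives", {}).items()},
        accepted=bool(d.get("accepted", False)),
        diagnostics={"theta": dict(d["theta"]), "seed": d.get("seed")},
    )
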