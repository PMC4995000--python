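"""Stage-indexed expression data, time mapping, smoothing and confidence bands.

Developmental stages of early T-cell precursors (ETP through DN3a) are
assigned calendar days using mean transit times: although a cell spends
~10 days in the ETP compartment, most ETP cells are produced near the
end of that window after several divisions, so successive stages are
separated by one day each:

    ETP -> day 0, ETP-DN2a -> day 1, DN2a -> day 2, DN2b -> day 3, DN3a -> day 4

Per-stage expression values carry a coefficient of variation (default
25%), from which 95% confidence intervals are built with a normal
approximation on the linear scale (a lognormal option is available).
Each gene's five-point series is smoothed with a positive parametric
curve -- baseline plus one logistic transition -- whose analytic
derivative feeds the constraint-derivation steps of calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import lmfit

__all__ = [
    "STAGES",
    "StageMap",
    "ExpressionSeries",
    "SmoothProfile",
    "stage_to_time",
    "time_to_stage",
    "smooth_series",
    "confidence_interval",
    "load_stage_csv",
    "write_stage_csv",
]

#: Ordered developmental stages and their day assignment.
STAGES: Tuple[str, ...] = ("ETP", "ETP-DN2a", "DN2a", "DN2b", "DN3a")
_STAGE_DAYS: Dict[str, float] = {s: float(i) for i, s in enumerate(STAGES)}


@dataclass(frozen=True)
class StageMap:
    """Mapping from developmental stage to day, strictly increasing."""

    days: Mapping[str, float] = field(default_factory=lambda: dict(_STAGE_DAYS))

    def __post_init__(self) -> None:
        if tuple(self.days) != STAGES:
            raise ValueError(f"stages must be exactly {STAGES} in order")
        vals = list(self.days.values())
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("day assignment must be strictly increasing")

    def __getitem__(self, stage: str) -> float:
        return self.days[stage]


def stage_to_time(stage: str) -> float:
    """Day assigned to a stage label (ETP=0 ... DN3a=4)."""
    try:
        return _STAGE_DAYS[stage]
    except KeyError:
        raise KeyError(
            f"unknown stage {stage!r}; valid stages are {', '.join(STAGES)}"
        ) from None


def time_to_stage(day: float) -> str:
    """Inverse of :func:`stage_to_time` on the five canonical days."""
    for stage, d in _STAGE_DAYS.items():
        if d == day:
            return stage
    raise KeyError(f"no stage at day {day!r}; valid days are 0..4")


@dataclass
class ExpressionSeries:
    """Time-stamped expression values for one gene with CV-based uncertainty."""

    gene: str
    times: np.ndarray
    values: np.ndarray
    cv: float = 0.25

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("expression values must be positive")
        if not (0 < self.cv < 1):
            raise ValueError("cv must lie in (0, 1)")

    def confidence_band(self, scale: str = "linear") -> Tuple[np.ndarray, np.ndarray]:
        los, his = [], []
        for v in self.values:
            lo, hi = confidence_interval(v, self.cv, scale=scale)
            los.append(lo)
            his.append(hi)
        return np.array(los), np.array(his)


# ---------------------------------------------------------------------------
# Parametric smoothing
# ---------------------------------------------------------------------------


def _curve(t, base, amp, t0, width):
    return base + amp / (1.0 + np.exp(-(t - t0) / width))


def _curve_deriv(t, base, amp, t0, width):
    z = np.exp(-(t - t0) / width)
    return amp * z / (width * (1.0 + z) ** 2)


@dataclass
class SmoothProfile:
    """Smoothed expression profile with analytic value and derivative."""

    gene: str
    params: Dict[str, float]

    def value(self, t):
        return _curve(np.asarray(t, dtype=float), **self.params)

    def derivative(self, t):
        return _curve_deriv(np.asarray(t, dtype=float), **self.params)

    def __call__(self, t):
        return self.value(t)


def smooth_series(series: ExpressionSeries) -> SmoothProfile:
    """Fit a baseline-plus-logistic curve to a series by least squares.

    The four parameters are the baseline, the transition amplitude
    (signed: negative for declining genes), the transition midpoint and
    width.  The fitted curve must stay positive on [0, 4].
    """
    t, y = series.times, series.values
    if len(t) < 4:
        raise ValueError("need at least 4 points to fit the smoother")

    span = float(y[-1] - y[0])
    p = lmfit.Parameters()
    p.add("base", value=float(y[0]), min=0.0)
    p.add("amp", value=span if abs(span) > 1e-12 * max(abs(y).max(), 1) else 0.0)
    p.add("t0", value=float(t[len(t) // 2]), min=float(t[0]) - 2, max=float(t[-1]) + 2)
    p.add("width", value=0.5, min=0.05, max=5.0)

    def resid(pars):
        return _curve(t, pars["base"], pars["amp"], pars["t0"], pars["width"]) - y

    out = lmfit.minimize(resid, p, method="leastsq")
    if not np.all(np.isfinite([out.params[k].value for k in out.params])):
        raise RuntimeError(f"degenerate smoother fit for gene {series.gene}")
    fitted = {k: float(out.params[k].value) for k in ("base", "amp", "t0", "width")}
    profile = SmoothProfile(gene=series.gene, params=fitted)

    grid = np.linspace(t[0], t[-1], 101)
    if np.any(profile.value(grid) <= 0):
        # fall back to a non-negative-baseline refit with amp bounded to keep
        # the curve positive (rare: strongly declining noisy series)
        p2 = lmfit.Parameters()
        p2.add("base", value=max(float(y.min()) * 0.5, 1e-9), min=1e-12)
        p2.add("amp", value=span, min=-float(y.max()), max=3 * float(y.max()))
        p2.add("t0", value=float(t[len(t) // 2]), min=float(t[0]) - 2, max=float(t[-1]) + 2)
        p2.add("width", value=0.5, min=0.05, max=5.0)
        out = lmfit.minimize(resid, p2, method="leastsq")
        fitted = {k: float(out.params[k].value) for k in ("base", "amp", "t0", "width")}
        profile = SmoothProfile(gene=series.gene, params=fitted)
        if np.any(profile.value(grid) <= 0):
            raise RuntimeError(
                f"smoother for gene {series.gene} is not positive on the fit window"
            )
    return profile


# ---------------------------------------------------------------------------
# Confidence intervals
# ---------------------------------------------------------------------------

_Z95 = 1.96


def confidence_interval(
    value: float, cv: float, scale: str = "linear"
) -> Tuple[float, float]:
    """95% confidence interval around ``value`` given a coefficient of variation.

    ``scale="linear"`` (default) uses the normal approximation
    value * (1 -/+ 1.96 cv), with the lower limit clipped at zero;
    ``scale="log"`` uses the lognormal form value * exp(-/+ 1.96 cv),
    matching errors estimated on log expression values.
    """
    if value <= 0:
        raise ValueError("value must be positive")
    if cv <= 0:
        raise ValueError("cv must be positive")
    if scale == "linear":
        lo = max(value * (1.0 - _Z95 * cv), 0.0)
        hi = value * (1.0 + _Z95 * cv)
    elif scale == "log":
        lo = value * np.exp(-_Z95 * cv)
        hi = value * np.exp(_Z95 * cv)
    else:
        raise ValueError("scale must be 'linear' or 'log'")
    return lo, hi


# ---------------------------------------------------------------------------
# CSV I/O (columns: stage, gene, value)
# ---------------------------------------------------------------------------


def load_stage_csv(path, cv: float = 0.25) -> List[ExpressionSeries]:
    """Read a stage,gene,value table into per-gene time series."""
    import pandas as pd

    frame = pd.read_csv(path)
    required = {"stage", "gene", "value"}
    if not required.issubset(frame.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    out = []
    for gene, grp in frame.groupby("gene", sort=False):
        days = grp["stage"].map(stage_to_time)
        order = np.argsort(days.to_numpy())
        out.append(
            ExpressionSeries(
                gene=str(gene),
                times=days.to_numpy()[order],
                values=grp["value"].to_numpy()[order],
                cv=cv,
            )
        )
    return out


def write_stage_csv(series_list: Sequence[ExpressionSeries], path) -> None:
    """Write per-gene series back to the stage,gene,value dialect."""
    import pandas as pd

    rows = []
    for s in series_list:
        for t, v in zip(s.times, s.values):
            rows.append((time_to_stage(t), s.gene, v))
    pd.DataFrame(rows, columns=["stage", "gene", "value"]).to_csv(path, index=False)
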