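"""Constrained two-leg parameter estimation.

The fitting workflow mirrors the structure of the commitment study:

1. *Notch-constraint bounds.*  With PU.1 clamped to its smoothed
   profile, each of the TCF-1, GATA-3 and BCL11B rate equations can be
   solved algebraically for the Notch-coupled production term implied by
   the observed level and derivative at each grid time.  Requiring that
   implied signal to be positive everywhere and to increase by at most a
   capped fold (default 3.5 between day 0 and day 4) carves out a
   feasible region of parameter space; its sampled envelope supplies
   box bounds for the optimiser.
2. *TGB leg.*  For a given combinatorial configuration, the TCF-1,
   GATA-3 and BCL11B equations are fitted simultaneously (equal-weight
   sum of per-gene residuals, each normalised by the gene's data
   maximum) with PU.1 clamped, by seeded simulated annealing inside the
   bounds followed by a local least-squares polish.  The Notch signal is
   parameterised directly by its fold increase, so the fold cap holds by
   construction.
3. *Filters.*  A fit is accepted only if the simulated trajectory lies
   within the 95% confidence band of every observed point for all three
   genes, and every (effective) protein half-life falls in a plausible
   window of hours.
4. *PU.1 leg.*  With TCF-1, GATA-3 and BCL11B clamped, positivity of
   the BCL11B level implied by inverting the PU.1 equation bounds the
   PU.1 parameters (Monte Carlo for the remainder); constrained
   simulated annealing under the ordering constraint rho4 <
   min(rho2, rho3) (BCL11B represses PU.1 more weakly than TCF-1 or
   GATA-3 do) then yields an ensemble of parameter sets that pass the
   confidence filter on PU.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import dual_annealing, least_squares

from .logic import LogicConfig, RateLaw, compile_rate_law
from .model import (
    GENES,
    GeneState,
    ModelParameters,
    ModelSpec,
    NotchSignal,
    SimulationError,
    simulate,
    rhs,
)
from .staging import ExpressionSeries, SmoothProfile, confidence_interval, smooth_series

__all__ = [
    "ParameterBounds",
    "FitResult",
    "Pu1Params",
    "InfeasibilityError",
    "derive_notch_bounds",
    "fit_tgb",
    "compute_half_life",
    "filter_fits",
    "derive_pu1_bounds",
    "fit_pu1",
    "default_bounds",
]

_LETTER_FROM_NAME = {"TCF-1": "T", "GATA-3": "G", "BCL11B": "B", "PU.1": "P"}

DEFAULT_FOLD_CAP = 3.5
DEFAULT_HL_WINDOW = (1.0, 48.0)  # hours; "order of hours"
_HOURS_PER_DAY = 24.0


class InfeasibilityError(RuntimeError):
    """No parameter values satisfy the constraints; names the equation."""

    def __init__(self, equation: str, message: str):
        super().__init__(f"{equation} equation: {message}")
        self.equation = equation


@dataclass
class ParameterBounds:
    """Per-parameter (lower, upper) box bounds."""

    bounds: Dict[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid bounds for {name}: ({lo}, {hi})")

    def __getitem__(self, name: str) -> Tuple[float, float]:
        return self.bounds[name]

    def __contains__(self, name: str) -> bool:
        return name in self.bounds

    def names(self) -> List[str]:
        return list(self.bounds)

    def contains_value(self, name: str, value: float) -> bool:
        lo, hi = self.bounds[name]
        return lo <= value <= hi

    def update(self, other: "ParameterBounds") -> "ParameterBounds":
        merged = dict(self.bounds)
        merged.update(other.bounds)
        return ParameterBounds(merged)


def series_map(
    data: Union[Mapping[str, ExpressionSeries], Sequence[ExpressionSeries]]
) -> Dict[str, ExpressionSeries]:
    """Normalise a dataset to a dict keyed by gene letters T/G/B/P."""
    if isinstance(data, Mapping):
        out = {}
        for key, s in data.items():
            out[_LETTER_FROM_NAME.get(key, key)] = s
        return out
    out = {}
    for s in data:
        letter = _LETTER_FROM_NAME.get(s.gene, s.gene)
        out[letter] = s
    return out


def _smooth_all(data: Mapping[str, ExpressionSeries]) -> Dict[str, SmoothProfile]:
    return {g: smooth_series(s) for g, s in data.items()}


# ---------------------------------------------------------------------------
# Notch-constraint bounds (leg A preliminaries)
# ---------------------------------------------------------------------------

_GRID_STEP = 0.1
_NOTCH_SAFETY = 10.0  # envelope widening for the sampled feasible set
_SAFETY = 2.0  # envelope widening factor for the PU.1 Monte Carlo bounds

# broad log-uniform priors for the Monte Carlo feasibility sampling, in
# natural "data units": decay rates per day, occupancy weights scaled so
# weight x (profile maximum) spans 1e-3 .. 1e3
_GAMMA_RANGE = (0.05, 30.0)
_WEIGHT_TIMES_MAX_RANGE = (1e-3, 1e3)
_CEILING_FACTOR_RANGE = (1.0, 100.0)


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _gamma_range_from_hl(hl_window: Tuple[float, float]) -> Tuple[float, float]:
    """Per-day decay-rate range compatible with a half-life window in hours."""
    lo = max(_GAMMA_RANGE[0], math.log(2.0) * _HOURS_PER_DAY / hl_window[1])
    hi = min(_GAMMA_RANGE[1], math.log(2.0) * _HOURS_PER_DAY / hl_window[0])
    return lo, hi


def _implied_notch_interval(implied: np.ndarray, fold_cap: float) -> Tuple[float, float]:
    """Bounds on the Notch-coupled weight from its implied profile.

    The implied values equal weight * nu(t) with nu in (0, 1] and
    nu(max)/nu(min) <= fold_cap, so the weight itself lies between the
    largest implied value and fold_cap times it.
    """
    top = float(np.max(implied))
    return top, fold_cap * top


def derive_notch_bounds(
    profiles: Mapping[str, SmoothProfile],
    config: LogicConfig,
    fixed: Optional[Mapping[str, float]] = None,
    fold_cap: float = DEFAULT_FOLD_CAP,
    n_samples: int = 4000,
    seed: int = 0,
    cv: float = 0.0,
    hl_window: Tuple[float, float] = DEFAULT_HL_WINDOW,
) -> ParameterBounds:
    """Parameter bounds implied by positivity and fold cap of Notch signalling.

    For each of the T, G and B equations the Notch-coupled production
    term is solved for on a 0.1-day grid given sampled values of the
    remaining parameters; a sample is feasible when the implied term is
    positive everywhere and varies by at most ``fold_cap``.  The envelope
    of feasible samples, widened by a safety factor, gives the bounds.  ``fixed`` pins parameters at known values (they are sampled
    as that single value and bounded at it).

    The fold condition is evaluated only at times where the equation's
    occupancy is resolved (at least 5% of its maximum over the window):
    where production sits below the smoothing resolution the implied
    term is a difference of near-zero quantities and its fold is
    numerically meaningless, while positivity is still enforced
    everywhere.  When the profiles come from noisy data, pass the data's
    coefficient of variation as ``cv``: the feasibility check then
    inflates the fold cap by the 95%-band ratio (1+1.96cv)/(1-1.96cv),
    since an implied fold measured between two noisy points carries that
    much multiplicative uncertainty.

    Raises :class:`InfeasibilityError` naming the offending equation when
    no sample is feasible -- for instance when a profile's derivative is
    more negative than -gamma * value so the implied signal would have to
    be negative.
    """
    fixed = dict(fixed or {})
    if not (0 <= cv < 0.5):
        raise ValueError("cv must lie in [0, 0.5) for the normal-band slack")
    fold_slack = (1.0 + 1.96 * cv) / (1.0 - 1.96 * cv)
    gamma_range = _gamma_range_from_hl(hl_window)
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 4.0 + 1e-9, _GRID_STEP)
    val = {g: profiles[g].value(t) for g in "TGBP"}
    der = {g: profiles[g].derivative(t) for g in "TGBP"}
    rate_law = compile_rate_law(config)

    out: Dict[str, Tuple[float, float]] = {}

    def run_equation(eq: str, unknown_weights: List[Tuple[str, object]], notch_name: str,
                     gamma_name: str, f_name: str, implied_fn) -> None:
        """Sample, keep feasible envelopes, write bounds for one equation."""
        x, dx = val[eq], der[eq]
        # fast analytic infeasibility: with a pinned decay rate the net
        # production D = x' + gamma x must be positive
        if gamma_name in fixed:
            D = dx + fixed[gamma_name] * x
            if np.any(D <= 0):
                raise InfeasibilityError(
                    eq,
                    "observed derivative more negative than -gamma*value; "
                    "implied Notch signal would be negative",
                )
        feasible: Dict[str, List[float]] = {
            name: [] for name, _ in unknown_weights
        }
        feasible[gamma_name] = []
        feasible[f_name] = []
        notch_lo, notch_hi = math.inf, -math.inf
        n_ok = 0
        for _ in range(n_samples):
            gamma = fixed.get(gamma_name, _loguniform(rng, *gamma_range))
            D = dx + gamma * x
            if np.any(D <= 0):
                continue
            ceiling = _loguniform(rng, *_CEILING_FACTOR_RANGE) * float(x.max())
            f_val = fixed.get(f_name, ceiling * gamma)
            r = D / f_val
            if np.any(r >= 0.995):
                continue
            weights = {}
            for name, sampler in unknown_weights:
                weights[name] = fixed.get(name, sampler(r))
            implied = implied_fn(r, weights)
            if implied is None or np.any(implied <= 0):
                continue
            resolved = r >= 0.05 * float(np.max(r))
            imp_res = implied[resolved]
            if float(np.max(imp_res)) / float(np.min(imp_res)) > fold_cap * fold_slack:
                continue
            n_ok += 1
            lo, hi = _implied_notch_interval(imp_res, fold_cap)
            notch_lo, notch_hi = min(notch_lo, lo), max(notch_hi, hi)
            for name, v in weights.items():
                feasible[name].append(v)
            feasible[gamma_name].append(gamma)
            feasible[f_name].append(f_val)
        if n_ok == 0:
            raise InfeasibilityError(
                eq, f"no feasible parameter sample in {n_samples} draws"
            )
        for name, vals in feasible.items():
            lo, hi = min(vals), max(vals)
            lo, hi = lo / _NOTCH_SAFETY, hi * _NOTCH_SAFETY
            if name == gamma_name:
                lo, hi = max(lo, gamma_range[0]), min(hi, gamma_range[1])
            out[name] = (lo, hi)
        out[notch_name] = (notch_lo / _NOTCH_SAFETY, notch_hi * _NOTCH_SAFETY)

    def plain_sampler(max_scale: float):
        lo, hi = _WEIGHT_TIMES_MAX_RANGE

        def sampler(r):
            return _loguniform(rng, lo, hi) / max_scale

        return sampler

    # --- TCF-1 equation: S = eta1N*nu + eta2*T + eta3*G, repressor eta4*P
    def implied_T(r, w):
        A = w["eta2"] * val["T"] + w["eta3"] * val["G"]
        R = w["eta4"] * val["P"]
        return (r * (1.0 + A + R) - A) / (1.0 - r)

    run_equation(
        "T",
        [("eta2", plain_sampler(float(val["T"].max()))),
         ("eta3", plain_sampler(float(val["G"].max()))),
         ("eta4", plain_sampler(float(val["P"].max())))],
        "eta1N", "gamma_T", "f_T", implied_T,
    )

    # --- GATA-3 equation: S = delta1N*nu + delta2*T, repressor delta3*P
    def implied_G(r, w):
        A = w["delta2"] * val["T"]
        R = w["delta3"] * val["P"]
        return (r * (1.0 + A + R) - A) / (1.0 - r)

    run_equation(
        "G",
        [("delta2", plain_sampler(float(val["T"].max()))),
         ("delta3", plain_sampler(float(val["P"].max())))],
        "delta1N", "gamma_G", "f_G", implied_G,
    )

    # --- BCL11B equation: S = sum_j kappa_j * minterm_j, Notch minterm first
    minterm_vals = []
    for minterm in rate_law.minterms:
        m = np.ones_like(t)
        for name, expo in minterm.items():
            if name == "TCF-1":
                m = m * val["T"] ** expo
            elif name == "GATA-3":
                m = m * val["G"] ** expo
        minterm_vals.append(m)
    has_notch = ["Notch" in mt for mt in rate_law.minterms]
    if not has_notch[0]:
        raise InfeasibilityError("B", "rate law has no Notch-coupled minterm")
    non_notch = [j for j in range(len(minterm_vals)) if not has_notch[j]]

    def implied_B(r, w):
        S = r / (1.0 - r)
        rest = np.zeros_like(t)
        for j in non_notch:
            rest = rest + w[f"kappa{j + 1}"] * minterm_vals[j]
        return (S - rest) / minterm_vals[0]

    def kappa_sampler(j: int):
        # condition on positivity: kappa_j cannot exceed min_t S/m_j
        mj = minterm_vals[j]

        def sampler(r):
            S = r / (1.0 - r)
            cap = float(np.min(S / mj))
            return cap * 10.0 ** (-rng.uniform(0.0, 4.0))

        return sampler

    run_equation(
        "B",
        [(f"kappa{j + 1}", kappa_sampler(j)) for j in non_notch],
        "kappa1", "gamma_B", "f_B", implied_B,
    )

    # Notch-shape parameters: structural ranges
    out["alpha"] = (0.05, 2.0)
    out["t_half"] = (0.0, 4.0)
    out["fold"] = (1.0, fold_cap)
    return ParameterBounds(out)


def default_bounds(
    data: Mapping[str, ExpressionSeries],
    config: LogicConfig,
    fold_cap: float = DEFAULT_FOLD_CAP,
    hl_window: Tuple[float, float] = DEFAULT_HL_WINDOW,
) -> ParameterBounds:
    """Broad fallback bounds scaled to the data, without feasibility sampling."""
    rate_law = compile_rate_law(config)
    sm = series_map(data)
    mx = {g: float(np.max(sm[g].values)) for g in "TGBP"}
    w = _WEIGHT_TIMES_MAX_RANGE
    _GAMMA_RANGE = _gamma_range_from_hl(hl_window)  # shadow: plausibility-narrowed
    out: Dict[str, Tuple[float, float]] = {
        "eta1N": (1e-3, 1e2),
        "eta2": (w[0] / mx["T"], w[1] / mx["T"]),
        "eta3": (w[0] / mx["G"], w[1] / mx["G"]),
        "eta4": (w[0] / mx["P"], w[1] / mx["P"]),
        "f_T": (_GAMMA_RANGE[0] * mx["T"], _GAMMA_RANGE[1] * mx["T"] * 100),
        "gamma_T": _GAMMA_RANGE,
        "delta1N": (1e-3, 1e2),
        "delta2": (w[0] / mx["T"], w[1] / mx["T"]),
        "delta3": (w[0] / mx["P"], w[1] / mx["P"]),
        "f_G": (_GAMMA_RANGE[0] * mx["G"], _GAMMA_RANGE[1] * mx["G"] * 100),
        "gamma_G": _GAMMA_RANGE,
        "f_B": (_GAMMA_RANGE[0] * mx["B"], _GAMMA_RANGE[1] * mx["B"] * 100),
        "gamma_B": _GAMMA_RANGE,
        "alpha": (0.05, 2.0),
        "t_half": (0.0, 4.0),
        "fold": (1.0, fold_cap),
    }
    for j, minterm in enumerate(rate_law.minterms, start=1):
        scale = 1.0
        for name, expo in minterm.items():
            if name == "TCF-1":
                scale *= mx["T"] ** expo
            elif name == "GATA-3":
                scale *= mx["G"] ** expo
        out[f"kappa{j}"] = (w[0] / scale, w[1] / scale)
    return ParameterBounds(out)


# ---------------------------------------------------------------------------
# TGB fitting (leg A)
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of one configuration's TGB fit plus downstream filters."""

    config: LogicConfig
    params: ModelParameters
    notch: NotchSignal
    objective: Dict[str, float]
    notch_fold: float
    ci_pass: Dict[str, bool] = field(default_factory=dict)
    half_lives: Dict[str, float] = field(default_factory=dict)
    accepted: bool = False
    diagnostics: Dict = field(default_factory=dict)

    @property
    def total_objective(self) -> float:
        return float(sum(self.objective.values()))

    def spec(self) -> ModelSpec:
        return ModelSpec(logic=self.config, params=self.params, notch=self.notch)


def _theta_names(rate_law: RateLaw) -> List[str]:
    names = ["eta1N", "eta2", "eta3", "eta4", "f_T", "gamma_T",
             "delta1N", "delta2", "delta3", "f_G", "gamma_G"]
    names += [f"kappa{j + 1}" for j in range(rate_law.n_minterms)]
    names += ["f_B", "gamma_B", "alpha", "t_half", "fold"]
    return names


def _build_spec(theta: Mapping[str, float], config: LogicConfig,
                rate_law: RateLaw) -> ModelSpec:
    params = ModelParameters(
        eta=(theta["eta1N"], theta["eta2"], theta["eta3"], theta["eta4"]),
        delta=(theta["delta1N"], theta["delta2"], theta["delta3"]),
        kappa=tuple(theta[f"kappa{j + 1}"] for j in range(rate_law.n_minterms)),
        f=(theta["f_T"], theta["f_G"], theta["f_B"], 0.0),
        gamma=(theta["gamma_T"], theta["gamma_G"], theta["gamma_B"], 1.0),
    )
    notch = NotchSignal.from_fold(
        fold=theta["fold"], alpha=theta["alpha"], t_half=theta["t_half"], n_max=1.0
    )
    return ModelSpec(logic=config, params=params, notch=notch)


_LINEAR_THETA = ("t_half", "fold")  # fitted on the linear scale; others log10


def _integrate_gene(
    deriv, x0: float, times: np.ndarray, rtol: float = 1e-6
) -> np.ndarray:
    """Light-weight scalar ODE integration used in the staged fits."""
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda t, x: [deriv(t, max(x[0], 0.0))],
        (times[0], times[-1]), [x0], method="LSODA",
        t_eval=times, rtol=rtol, atol=1e-9,
    )
    if not sol.success:
        raise SimulationError(f"integration failed: {sol.message}")
    return np.clip(sol.y[0], 0.0, None)


class _Transform:
    """Map between a named theta dict and a (log10-scaled) search vector."""

    def __init__(self, names: Sequence[str], bounds: ParameterBounds):
        self.names = list(names)
        self.lo = np.empty(len(self.names))
        self.hi = np.empty(len(self.names))
        for i, n in enumerate(self.names):
            l, h = bounds[n]
            if n in _LINEAR_THETA:
                self.lo[i], self.hi[i] = l, h
            else:
                l = max(l, 1e-300)
                self.lo[i] = np.log10(l)
                self.hi[i] = np.log10(max(h, l * (1 + 1e-12)))
            if self.hi[i] - self.lo[i] < 1e-9:
                self.hi[i] = self.lo[i] + 1e-9

    def unpack(self, z: np.ndarray) -> Dict[str, float]:
        return {
            n: (float(z[i]) if n in _LINEAR_THETA else float(10.0 ** z[i]))
            for i, n in enumerate(self.names)
        }

    def pack(self, theta: Mapping[str, float]) -> np.ndarray:
        z = np.empty(len(self.names))
        for i, n in enumerate(self.names):
            v = theta[n]
            z[i] = v if n in _LINEAR_THETA else np.log10(max(v, 1e-300))
        return np.clip(z, self.lo, self.hi)

    @property
    def box(self):
        return list(zip(self.lo, self.hi))


def _anneal_and_polish(residual_fn, transform: _Transform, seed: int,
                       maxiter: int) -> Dict[str, float]:
    def objective(z):
        r = residual_fn(z)
        return float(r @ r)

    result = dual_annealing(
        objective, bounds=transform.box, seed=seed, maxiter=maxiter,
        no_local_search=True,
    )
    polish = least_squares(
        residual_fn, np.clip(result.x, transform.lo, transform.hi),
        bounds=(transform.lo, transform.hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=120,
    )
    z = polish.x if objective(polish.x) <= objective(result.x) else result.x
    return transform.unpack(z)


def fit_tgb(
    config: LogicConfig,
    data: Union[Mapping[str, ExpressionSeries], Sequence[ExpressionSeries]],
    bounds: ParameterBounds,
    seed: int,
    maxiter: int = 120,
    rtol: float = 1e-6,
) -> FitResult:
    """Fit the TCF-1/GATA-3/BCL11B subsystem with PU.1 clamped.

    Minimises the equal-weight sum over the three genes of squared
    residuals normalised by each gene's data maximum.  The search runs
    in stages to keep the annealing dimension low: the TCF-1 equation
    (which carries the Notch-shape parameters) is fitted first with
    GATA-3 and PU.1 clamped to their smoothed profiles, then the GATA-3
    and BCL11B equations with the signal shape frozen, and finally all
    parameters are polished jointly on the coupled three-gene system by
    bounded least squares.  Positive parameters are searched in log10
    space; the Notch fold cap holds by construction of the signal
    parameterisation.  Deterministic given ``seed``.
    """
    sm = series_map(data)
    for g in "TGBP":
        if g not in sm:
            raise ValueError(f"data must contain all four genes; missing {g}")
    rate_law = compile_rate_law(config)
    names = _theta_names(rate_law)
    profiles = {g: smooth_series(sm[g]) for g in "TGBP"}
    p_profile = profiles["P"]

    times = sm["T"].times
    obs = {g: sm[g].values for g in "TGB"}
    norm = {g: float(np.max(obs[g])) for g in "TGB"}
    # within-gene weighting is relative (per-point), matching the relative
    # 95% confidence bands the filter checks; the reported objective uses
    # the max-normalised convention
    rel = {g: np.maximum(obs[g], 1e-12) for g in "TGB"}
    init = GeneState(obs["T"][0], obs["G"][0], obs["B"][0], float(p_profile.value(0.0)))
    prof_fn = {g: (lambda t, _p=profiles[g]: float(_p.value(t))) for g in "TGBP"}

    rng = np.random.default_rng(seed)
    sub_seeds = [int(rng.integers(0, 2**31 - 1)) for _ in range(3)]

    # --- stage 1: TCF-1 equation (carries the Notch shape) --------------
    t_names = ["eta1N", "eta2", "eta3", "eta4", "f_T", "gamma_T",
               "alpha", "t_half", "fold"]
    t_tr = _Transform(t_names, bounds)

    def t_resid(z):
        th = t_tr.unpack(z)
        notch = NotchSignal.from_fold(fold=th["fold"], alpha=th["alpha"],
                                      t_half=th["t_half"])

        def deriv(t, T):
            nu = notch.scale(t)
            G, P = prof_fn["G"](t), prof_fn["P"](t)
            num = th["eta1N"] * nu + th["eta2"] * T + th["eta3"] * G
            return th["f_T"] * num / (1.0 + num + th["eta4"] * P) - th["gamma_T"] * T

        try:
            sim = _integrate_gene(deriv, obs["T"][0], times, rtol=rtol)
        except SimulationError:
            return np.full(len(times), 1e3)
        return (sim - obs["T"]) / rel["T"]

    theta = _anneal_and_polish(t_resid, t_tr, sub_seeds[0], maxiter)
    notch = NotchSignal.from_fold(fold=theta["fold"], alpha=theta["alpha"],
                                  t_half=theta["t_half"])

    # --- stage 2: GATA-3 equation with the signal frozen -----------------
    g_names = ["delta1N", "delta2", "delta3", "f_G", "gamma_G"]
    g_tr = _Transform(g_names, bounds)

    def g_resid(z):
        th = g_tr.unpack(z)

        def deriv(t, G):
            nu = notch.scale(t)
            T, P = prof_fn["T"](t), prof_fn["P"](t)
            num = th["delta1N"] * nu + th["delta2"] * T
            return th["f_G"] * num / (1.0 + num + th["delta3"] * P) - th["gamma_G"] * G

        try:
            sim = _integrate_gene(deriv, obs["G"][0], times, rtol=rtol)
        except SimulationError:
            return np.full(len(times), 1e3)
        return (sim - obs["G"]) / rel["G"]

    theta.update(_anneal_and_polish(g_resid, g_tr, sub_seeds[1], maxiter))

    # --- stage 3: BCL11B equation with the signal frozen -----------------
    b_names = [f"kappa{j + 1}" for j in range(rate_law.n_minterms)] + ["f_B", "gamma_B"]
    b_tr = _Transform(b_names, bounds)

    def b_resid(z):
        th = b_tr.unpack(z)
        kappas = [th[f"kappa{j + 1}"] for j in range(rate_law.n_minterms)]

        def deriv(t, B):
            nu = notch.scale(t)
            T, G = prof_fn["T"](t), prof_fn["G"](t)
            S = 0.0
            for kappa, minterm in zip(kappas, rate_law.minterms):
                term = kappa
                for name, expo in minterm.items():
                    if name == "Notch":
                        term *= nu
                    elif name == "TCF-1":
                        term *= T**expo
                    else:
                        term *= G**expo
                S += term
            return th["f_B"] * S / (1.0 + S) - th["gamma_B"] * B

        try:
            sim = _integrate_gene(deriv, obs["B"][0], times, rtol=rtol)
        except SimulationError:
            return np.full(len(times), 1e3)
        return (sim - obs["B"]) / rel["B"]

    theta.update(_anneal_and_polish(b_resid, b_tr, sub_seeds[2], maxiter))

    # --- stage 4: joint polish on the coupled system ---------------------
    full_tr = _Transform(names, bounds)

    def full_resid(z):
        th = full_tr.unpack(z)
        try:
            spec = _build_spec(th, config, rate_law)
            traj = simulate(
                spec, init, times,
                clamps={"P": prof_fn["P"]},
                rtol=rtol, atol=1e-9,
            )
        except (SimulationError, ValueError):
            return np.full(3 * len(times), 1e3)
        return np.concatenate([(traj[g] - obs[g]) / rel[g] for g in "TGB"])

    z0 = full_tr.pack(theta)
    polish = least_squares(
        full_resid, z0, bounds=(full_tr.lo, full_tr.hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=150,
    )
    r0 = full_resid(z0)
    z_best = polish.x if float(polish.fun @ polish.fun) <= float(r0 @ r0) else z0
    theta = full_tr.unpack(z_best)
    spec = _build_spec(theta, config, rate_law)
    traj = simulate(
        spec, init, times,
        clamps={"P": lambda t: float(p_profile.value(t))},
        rtol=1e-8, atol=1e-10,
    )
    per_gene = {
        g: float(np.sum(((traj[g] - obs[g]) / norm[g]) ** 2)) for g in "TGB"
    }
    fit = FitResult(
        config=config,
        params=spec.params,
        notch=spec.notch,
        objective=per_gene,
        notch_fold=spec.notch.fold(0.0, 4.0),
        diagnostics={
            "theta": theta,
            "trajectory": traj,
            "p_profile": p_profile,
            "converged": bool(polish.success),
            "seed": seed,
        },
    )
    return fit


# ---------------------------------------------------------------------------
# Half-lives
# ---------------------------------------------------------------------------


def compute_half_life(
    model: Union[ModelParameters, ModelSpec],
    gene: str,
    mode: str = "intrinsic",
    state: Optional[GeneState] = None,
    nu: float = 1.0,
) -> float:
    """Protein half-life in hours.

    ``intrinsic`` mode returns ln2/gamma (decay alone).  ``effective``
    mode linearises the full net decay at ``state`` -- gamma minus the
    production Jacobian diagonal -- capturing self-feedback; it requires
    a full :class:`ModelSpec` and an expansion state (typically the
    fitted day-4 state).  A nonpositive linearised decay (an unstable
    direction) yields ``math.inf``.  Rates are per day; the result is in
    hours.
    """
    if gene not in GENES:
        raise ValueError(f"gene must be one of {GENES}")
    i = GENES.index(gene)
    params = model.params if isinstance(model, ModelSpec) else model
    gamma = params.gamma[i]
    if mode == "intrinsic":
        return math.log(2.0) / gamma * _HOURS_PER_DAY
    if mode != "effective":
        raise ValueError("mode must be 'intrinsic' or 'effective'")
    if not isinstance(model, ModelSpec):
        raise ValueError("effective mode requires a full ModelSpec")
    if state is None:
        raise ValueError("effective mode requires the expansion state")
    x0 = np.asarray(state, dtype=float)
    h = 1e-6 * max(abs(x0[i]), 1e-6 * max(params.ceiling(gene), 1.0))
    xp, xm = x0.copy(), x0.copy()
    xp[i] += h
    xm[i] = max(xm[i] - h, 0.0)
    dp = rhs(xp, 0.0, model, nu=nu)[i]
    dm = rhs(xm, 0.0, model, nu=nu)[i]
    jac_diag = (dp - dm) / (xp[i] - xm[i])  # = -gamma + d(production)/dX
    net_decay = -jac_diag
    if net_decay <= 0:
        return math.inf
    return math.log(2.0) / net_decay * _HOURS_PER_DAY


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_fits(
    fits: Sequence[FitResult],
    data: Union[Mapping[str, ExpressionSeries], Sequence[ExpressionSeries]],
    cv: float = 0.25,
    hl_window: Tuple[float, float] = DEFAULT_HL_WINDOW,
    hl_mode: str = "effective",
    ci_scale: str = "linear",
) -> List[FitResult]:
    """Apply the confidence-interval and half-life plausibility filters.

    A fit passes when, for each of TCF-1, GATA-3 and BCL11B, the
    simulated trajectory lies inside the 95% confidence interval of
    every observed point, and every half-life falls within
    ``hl_window`` (hours).  Each fit's ``ci_pass``, ``half_lives`` and
    ``accepted`` fields are updated in place; the accepted subset is
    returned.  Widening ``cv`` or ``hl_window`` never removes a fit.
    """
    if not (0 < cv < 1):
        raise ValueError("cv must lie in (0, 1)")
    if hl_window[0] <= 0 or hl_window[1] <= hl_window[0]:
        raise ValueError("hl_window must be a positive increasing pair")
    sm = series_map(data)
    accepted = []
    for fit in fits:
        traj = fit.diagnostics.get("trajectory")
        if traj is None:
            p_profile = fit.diagnostics.get("p_profile") or smooth_series(sm["P"])
            init = GeneState(
                sm["T"].values[0], sm["G"].values[0], sm["B"].values[0],
                float(p_profile.value(0.0)),
            )
            traj = simulate(
                fit.spec(), init, sm["T"].times,
                clamps={"P": lambda t: float(p_profile.value(t))},
            )
            fit.diagnostics["trajectory"] = traj
        ci_pass = {}
        for g in "TGB":
            ok = True
            for v_obs, v_sim in zip(sm[g].values, traj[g]):
                lo, hi_ = confidence_interval(v_obs, cv, scale=ci_scale)
                if not (lo <= v_sim <= hi_):
                    ok = False
                    break
            ci_pass[g] = ok
        spec = fit.spec()
        day4 = traj.state_at(-1)
        hls = {}
        for g in "TGB":
            if hl_mode == "effective":
                hls[g] = compute_half_life(
                    spec, g, mode="effective", state=day4, nu=spec.notch.scale(4.0)
                )
            else:
                hls[g] = compute_half_life(spec.params, g, mode="intrinsic")
        fit.ci_pass = ci_pass
        fit.half_lives = hls
        # boundary tolerance: decay rates legitimately sit on the bounds
        # implied by the window itself, so the comparison must not reject
        # on float rounding
        hl_lo, hl_hi = hl_window[0] * (1 - 1e-9), hl_window[1] * (1 + 1e-9)
        fit.accepted = (
            all(ci_pass.values())
            and all(hl_lo <= h <= hl_hi for h in hls.values())
            and fit.notch_fold <= DEFAULT_FOLD_CAP + 1e-9
        )
        if fit.accepted:
            accepted.append(fit)
    return accepted


# ---------------------------------------------------------------------------
# PU.1 leg (leg B)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pu1Params:
    """One PU.1 parameter set: self-activation, repression weights, rates."""

    rho: Tuple[float, float, float, float]
    f_P: float
    gamma_P: float

    def apply(self, params: ModelParameters) -> ModelParameters:
        f = list(params.f)
        gamma = list(params.gamma)
        f[3], gamma[3] = self.f_P, self.gamma_P
        return replace(params, rho=self.rho, f=tuple(f), gamma=tuple(gamma))


_PU1_NAMES = ("rho1", "rho2", "rho3", "rho4", "f_P", "gamma_P")


def _simulate_pu1_trajectory(
    pu1: Pu1Params,
    profiles: Mapping[str, SmoothProfile],
    p_series: ExpressionSeries,
    runx_input: float = 0.0,
) -> np.ndarray:
    """PU.1 trajectory at the observation times with T, G, B clamped."""
    from .logic import get_configuration

    params = ModelParameters(
        eta=(0.0,) * 4, delta=(0.0,) * 3, kappa=(0.0,),
        f=(0.0, 0.0, 0.0, pu1.f_P), gamma=(1.0, 1.0, 1.0, pu1.gamma_P),
        rho=pu1.rho, runx_input=runx_input,
    )
    # the logic configuration is irrelevant here (BCL11B is clamped); any
    # single-minterm form keeps the spec well-formed
    spec = ModelSpec(logic=get_configuration("8b"), params=params,
                     notch=NotchSignal())
    clamps = {g: (lambda t, _p=profiles[g]: float(_p.value(t))) for g in "TGB"}
    init = GeneState(
        clamps["T"](0.0), clamps["G"](0.0), clamps["B"](0.0),
        float(p_series.values[0]),
    )
    traj = simulate(spec, init, p_series.times, clamps=clamps,
                    rtol=1e-7, atol=1e-10)
    return traj["P"]


def derive_pu1_bounds(
    profiles: Mapping[str, SmoothProfile],
    n_mc: int,
    seed: int,
    runx_input: float = 0.0,
    grid_step: float = _GRID_STEP,
    max_draws: Optional[int] = None,
) -> ParameterBounds:
    """Bounds on the PU.1 parameters from BCL11B-positivity inversion.

    Inverting the PU.1 equation with TCF-1, GATA-3 and BCL11B clamped
    expresses the implied repression term rho4*B(t) as a function of the
    remaining PU.1 parameters and the observed PU.1 profile; requiring
    it to be positive on a ``grid_step``-day grid (default 0.1) rejects
    infeasible parameter draws -- a finer grid means more constraints
    and weakly tighter bounds.  Analytic necessary bounds (gamma_P from
    derivative positivity, f_P from occupancy < 1) seed the sampling;
    the envelope of the feasible Monte Carlo samples (at least ``n_mc``
    of them are required among ``max_draws`` draws), widened by a safety
    factor of 2, gives the remaining bounds.  The number of draws
    examined is fixed, so runs with the same seed see the same candidate
    stream regardless of the constraint grid.  Deterministic given
    ``seed``.
    """
    if n_mc <= 0:
        raise ValueError("n_mc must be a positive number of feasible samples")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, 4.0 + 1e-9, grid_step)
    P, dP = profiles["P"].value(t), profiles["P"].derivative(t)
    T, G, B = (profiles[g].value(t) for g in "TGB")
    mx = {"P": float(P.max()), "T": float(T.max()), "G": float(G.max()),
          "B": float(B.max())}

    # analytic necessary pieces
    gamma_floor = max(float(np.max(-dP / P)), 0.0) + 1e-12

    feasible: Dict[str, List[float]] = {n: [] for n in _PU1_NAMES}
    if max_draws is None:
        max_draws = max(100 * n_mc, 20000)
    for _ in range(max_draws):
        # all randomness is drawn up front so the stream stays aligned
        # across different constraint grids (enables nesting guarantees)
        gamma_P = _loguniform(rng, *_GAMMA_RANGE)  # D > 0 below enforces the floor
        ceiling = _loguniform(rng, *_CEILING_FACTOR_RANGE) * mx["P"]
        rho1 = _loguniform(rng, *_WEIGHT_TIMES_MAX_RANGE) / mx["P"]
        rho2 = _loguniform(rng, *_WEIGHT_TIMES_MAX_RANGE) / mx["T"]
        rho3 = _loguniform(rng, *_WEIGHT_TIMES_MAX_RANGE) / mx["G"]
        D = dP + gamma_P * P
        if np.any(D <= 0):
            continue
        f_P = ceiling * gamma_P
        r = D / f_P
        if np.any(r >= 0.995):
            continue
        num = rho1 * P + runx_input
        implied_rho4B = num * (1.0 - r) / r - 1.0 - rho2 * T - rho3 * G
        if np.any(implied_rho4B <= 0):
            continue
        # the per-sample rho4 range is read off at the five observation
        # days only, so that refining the positivity grid adds
        # constraints without widening any sample's contribution
        anchor = np.isin(np.round(t, 9), np.arange(0.0, 5.0))
        rho4_profile = implied_rho4B[anchor] / B[anchor]
        rho4_lo, rho4_hi = float(rho4_profile.min()), float(rho4_profile.max())
        feasible["rho1"].append(rho1)
        feasible["rho2"].append(rho2)
        feasible["rho3"].append(rho3)
        feasible["rho4"].append(rho4_lo)
        feasible["rho4"].append(rho4_hi)
        feasible["f_P"].append(f_P)
        feasible["gamma_P"].append(gamma_P)
    if len(feasible["rho1"]) < n_mc:
        raise InfeasibilityError(
            "P",
            f"only {len(feasible['rho1'])} feasible samples in {max_draws} draws",
        )
    out = {}
    for name in _PU1_NAMES:
        vals = feasible[name]
        out[name] = (min(vals) / _SAFETY, max(vals) * _SAFETY)
    lo, hi = out["gamma_P"]
    out["gamma_P"] = (max(lo, gamma_floor), hi)
    return ParameterBounds(out)


def fit_pu1(
    data: Union[Mapping[str, ExpressionSeries], Sequence[ExpressionSeries]],
    bounds: ParameterBounds,
    n_starts: int,
    seed: int,
    maxiter: int = 80,
    cv: float = 0.25,
    ci_scale: str = "linear",
    max_keep: int = 200,
    runx_input: float = 0.0,
) -> List[Pu1Params]:
    """Estimate PU.1 parameter ensembles with the other genes clamped.

    Runs constrained simulated annealing from ``n_starts`` seeded
    initialisations under the ordering constraint rho4 < min(rho2, rho3)
    (enforced by parameterising rho4 as a fraction of that minimum), and
    keeps every distinct solution whose simulated PU.1 trajectory passes
    the 95% confidence filter.  Returns up to ``max_keep`` sets.
    """
    sm = series_map(data)
    profiles = {g: smooth_series(sm[g]) for g in "TGB"}
    times = sm["P"].times
    obs = sm["P"].values
    norm = float(np.max(obs))

    names = ["rho1", "rho2", "rho3", "frac4", "f_P", "gamma_P"]
    lo = np.empty(6)
    hi = np.empty(6)
    for i, n in enumerate(names):
        if n == "frac4":
            lo[i], hi[i] = -3.0, np.log10(0.999)  # fraction of min(rho2, rho3)
        else:
            l, h = bounds[n]
            lo[i], hi[i] = np.log10(max(l, 1e-300)), np.log10(max(h, 1e-299))

    def unpack(z: np.ndarray) -> Pu1Params:
        v = {n: 10.0 ** z[i] for i, n in enumerate(names)}
        rho4 = v["frac4"] * min(v["rho2"], v["rho3"])
        return Pu1Params(
            rho=(v["rho1"], v["rho2"], v["rho3"], rho4),
            f_P=v["f_P"], gamma_P=v["gamma_P"],
        )

    def simulate_p(pu1: Pu1Params) -> np.ndarray:
        return _simulate_pu1_trajectory(
            pu1, profiles, sm["P"], runx_input=runx_input
        )

    def objective(z: np.ndarray) -> float:
        try:
            p_sim = simulate_p(unpack(z))
        except (SimulationError, ValueError):
            return 1e6
        r = (p_sim - obs) / norm
        return float(r @ r)

    keep: List[Pu1Params] = []
    seen: List[np.ndarray] = []
    rng = np.random.default_rng(seed)
    for k in range(n_starts):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        result = dual_annealing(
            objective, bounds=list(zip(lo, hi)), seed=sub_seed,
            maxiter=maxiter, no_local_search=True,
        )
        def resid(z):
            try:
                return (simulate_p(unpack(z)) - obs) / norm
            except (SimulationError, ValueError):
                return np.full(len(obs), 1e3)
        polish = least_squares(
            resid, np.clip(result.x, lo, hi), bounds=(lo, hi),
            method="trf", xtol=1e-10, ftol=1e-10, max_nfev=200,
        )
        z = polish.x if objective(polish.x) <= objective(result.x) else result.x
        pu1 = unpack(z)
        try:
            p_sim = simulate_p(pu1)
        except (SimulationError, ValueError):
            continue
        ok = all(
            confidence_interval(v_obs, cv, scale=ci_scale)[0]
            <= v_sim
            <= confidence_interval(v_obs, cv, scale=ci_scale)[1]
            for v_obs, v_sim in zip(obs, p_sim)
        )
        if not ok:
            continue
        if any(np.allclose(z, z_prev, rtol=1e-3, atol=1e-3) for z_prev in seen):
            continue
        seen.append(z)
        keep.append(pu1)
        if len(keep) >= max_keep:
            break
    return keep
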