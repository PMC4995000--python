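"""tcommit: dynamical modelling of T-cell lineage commitment.

A four-gene regulatory network (TCF-1, GATA-3, BCL11B, PU.1) driven by
Notch signalling, with combinatorial regulatory logic for BCL11B
compiled into Shea-Ackers rate equations, a constrained two-leg fitting
workflow, solution filters, and bifurcation analysis that classifies
commitment as reversible or irreversible.
"""

from .logic import (
    LogicConfig,
    RateLaw,
    compile_rate_law,
    enumerate_configurations,
    get_configuration,
    production_ratio,
)
from .model import (
    GeneState,
    ModelParameters,
    ModelSpec,
    NotchSignal,
    Trajectory,
    notch_signal,
    rhs,
    simulate,
    steady_state,
)
from .staging import (
    ExpressionSeries,
    SmoothProfile,
    StageMap,
    confidence_interval,
    smooth_series,
    stage_to_time,
)
from .params import demo_spec, winning_spec, WINNING_VARIANTS
from .synthetic import SyntheticDataset, generate_reference_dataset, generate_from_model

__all__ = [
    "LogicConfig",
    "RateLaw",
    "compile_rate_law",
    "enumerate_configurations",
    "get_configuration",
    "production_ratio",
    "GeneState",
    "ModelParameters",
    "ModelSpec",
    "NotchSignal",
    "Trajectory",
    "notch_signal",
    "rhs",
    "simulate",
    "steady_state",
    "ExpressionSeries",
    "SmoothProfile",
    "StageMap",
    "confidence_interval",
    "smooth_series",
    "stage_to_time",
    "demo_spec",
    "winning_spec",
    "WINNING_VARIANTS",
    "SyntheticDataset",
    "generate_reference_dataset",
    "generate_from_model",
    "CommitmentModel",
    "CommitmentResults",
]

__version__ = "0.1.0"


def __getattr__(name):
    # estimation imports calibration/commitment lazily to keep import light
    if name in ("CommitmentModel", "CommitmentResults"):
        from . import estimation

        return getattr(estimation, name)
    raise AttributeError(f"module 'tcommit' has no attribute {name!r}")
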