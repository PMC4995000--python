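"""Bifurcation sweeps, commitment classification, steady-set selection."""

import numpy as np
import pytest

from tcommit.calibration import Pu1Params
from tcommit.commitment import (
    bifurcation_scan,
    bistable_region,
    classify_commitment,
    find_steady_states,
    select_steady_sets,
)
from tcommit.logic import compile_rate_law, get_configuration
from tcommit.model import (
    GeneState,
    ModelParameters,
    ModelSpec,
    NotchSignal,
    steady_state,
)


def _committed(spec, clamps=None):
    c = spec.ceilings()
    state, _ = steady_state(
        spec, spec.notch.n_max,
        GeneState(0.9 * c["T"], 0.9 * c["G"], 0.9 * c["B"],
                  0.0 if clamps else 0.0),
        clamps=clamps,
    )
    return state


def _sweeps(spec, n_points=51, clamps=None):
    committed = _committed(spec, clamps=clamps)
    down = bifurcation_scan(spec, committed, "down", n_points=n_points,
                            clamps=clamps, chart_extra=False)
    c = spec.ceilings()
    low = GeneState(1e-6 * c["T"], 1e-6 * c["G"], 1e-6 * c["B"], 0.0)
    up = bifurcation_scan(spec, low, "up", n_points=n_points,
                          clamps=clamps, chart_extra=False)
    return down, up


class TestHeadlineClassification:
    def test_three_of_four_winning_configs_lock_bcl11b(self, winning_specs):
        verdicts = {}
        for vid, spec in winning_specs.items():
            down, up = _sweeps(spec, n_points=101, clamps={"P": 0.0})
            verdicts[vid] = classify_commitment(down, up)["B"]
        assert verdicts["8b"] == "reversible"
        for vid in ("6d", "7b", "7d"):
            assert verdicts[vid] == "irreversible", vid

    def test_all_and_gate_shuts_bcl11b_at_zero_notch(self, winning_specs):
        spec = winning_specs["8b"]
        down, _ = _sweeps(spec, n_points=51, clamps={"P": 0.0})
        assert down.value_at("B", 0.0) < 1e-6 * down.value_at("B", 1.0)

    def test_notch_gated_rate_laws_are_zero_without_signal(self, winning_specs):
        # analytic: if every minterm contains Notch, production is 0 at s=0
        law = compile_rate_law(get_configuration("8b"))
        assert all("Notch" in m for m in law.minterms)
        spec = winning_specs["8b"]
        state, _ = steady_state(
            spec, 0.0, _committed(spec, clamps={"P": 0.0}), clamps={"P": 0.0}
        )
        assert state.B == pytest.approx(0.0, abs=1e-12)

    def test_day_scale_model_is_also_irreversible(self, reference_spec):
        down, up = _sweeps(reference_spec, n_points=51, clamps={"P": 0.0})
        assert classify_commitment(down, up)["B"] == "irreversible"


class TestPu1Reactivation:
    def test_pu1_never_reactivates_without_external_drive(self, reference_spec):
        committed = _committed(reference_spec)  # free P; drops to ~0
        start = GeneState(committed.T, committed.G, committed.B, 0.0)
        down = bifurcation_scan(reference_spec, start, "down", n_points=21,
                                chart_extra=False)
        assert np.all(down.gene_branch("P") == 0.0)
        cls = classify_commitment(down)
        assert cls["P"] == "irreversible-off"

    def test_constant_external_drive_still_keeps_pu1_low(self, reference_spec):
        from dataclasses import replace

        spec = replace(
            reference_spec,
            params=replace(reference_spec.params, runx_input=0.05),
        )
        committed, _ = steady_state(spec, 1.0, GeneState(50, 40, 20, 1.0))
        down = bifurcation_scan(spec, committed, "down", n_points=21,
                                chart_extra=False)
        assert np.all(down.gene_branch("P") < 0.5 * spec.params.ceiling("P"))


class TestDiagrams:
    def test_zero_production_gives_origin_branch(self):
        spec = ModelSpec(
            logic=get_configuration("8b"),
            params=ModelParameters(
                eta=(0,) * 4, delta=(0,) * 3, kappa=(0.0,),
                f=(0, 0, 0, 0), gamma=(1.0,) * 4,
            ),
            notch=NotchSignal(),
        )
        down = bifurcation_scan(spec, GeneState(0, 0, 0, 0), "down",
                                n_points=11, chart_extra=False)
        assert np.allclose(down.branch, 0.0, atol=1e-10)

    def test_minimum_resolution_enforced(self, reference_spec):
        with pytest.raises(ValueError):
            bifurcation_scan(reference_spec, GeneState(0, 0, 0, 0), "down",
                             n_points=5)

    def test_continuation_agrees_with_multistart_roots(self, reference_spec):
        committed = _committed(reference_spec, clamps={"P": 0.0})
        down = bifurcation_scan(reference_spec, committed, "down", n_points=11,
                                clamps={"P": 0.0}, chart_extra=True,
                                n_multistart=20, seed=1)
        for j, s in enumerate(down.s_grid):
            states = down.extra_states[j]
            stable_states = [st for st, ok in states if ok]
            branch_point = down.branch[:, j]
            best = min(
                stable_states,
                key=lambda st: np.max(np.abs(np.asarray(st) - branch_point)),
            )
            for i in range(4):
                denom = max(abs(branch_point[i]), 1e-9)
                assert abs(best[i] - branch_point[i]) / denom < 1e-4

    def test_hysteresis_consistency(self, reference_spec, winning_specs):
        """Wherever stable up/down branches differ an unstable separatrix
        must sit between them; where they coincide the two continuations
        must land on the same attractor.  (With PU.1 clamped and monomer
        TCF-1/GATA-3 equations the subsystem has a unique stable branch,
        so the sweeps are expected to coincide here.)"""
        for spec in [reference_spec, winning_specs["6d"]]:
            down, up = _sweeps(spec, n_points=21, clamps={"P": 0.0})
            for g in "TGB":
                region = bistable_region(down, up, g)
                if region:
                    s_mid = region[len(region) // 2]
                    states = find_steady_states(spec, s_mid, clamps={"P": 0.0},
                                                n_starts=40, seed=2)
                    assert any(not stable for _, stable in states)
                else:
                    d = down.gene_branch(g)
                    u = up.gene_branch(g)[::-1]
                    denom = np.maximum(np.maximum(np.abs(d), np.abs(u)), 1e-9)
                    assert np.all(np.abs(d - u) / denom < 1e-4)

    def test_multistart_charts_coexisting_states_with_stability(self):
        # a PU.1 self-activation toggle: P = 0 is steady but unstable
        # (f*rho1 > gamma), and a stable high state coexists at P = 90
        spec = ModelSpec(
            logic=get_configuration("8b"),
            params=ModelParameters(
                eta=(0,) * 4, delta=(0,) * 3, kappa=(0.0,),
                f=(0, 0, 0, 120.0), gamma=(1.0, 1.0, 1.0, 1.2),
                rho=(0.1, 0.0, 0.0, 0.0),
            ),
            notch=NotchSignal(),
        )
        states = find_steady_states(spec, 1.0, n_starts=30, seed=3,
                                    include=[GeneState(0, 0, 0, 0)])
        p_values = sorted((round(st.P, 3), stable) for st, stable in states)
        assert (0.0, False) in p_values
        assert any(abs(p - 90.0) < 1e-3 and stable for p, stable in p_values)

    def test_identical_sweeps_report_no_bistable_region(self, reference_spec):
        down, _ = _sweeps(reference_spec, n_points=21, clamps={"P": 0.0})
        assert bistable_region(down, down, "B") == []

    def test_tidy_serialization(self, reference_spec):
        committed = _committed(reference_spec, clamps={"P": 0.0})
        down = bifurcation_scan(reference_spec, committed, "down", n_points=11,
                                clamps={"P": 0.0}, chart_extra=False)
        frame = down.to_frame()
        assert set(frame.columns) == {"s", "gene", "branch_id", "value", "stable"}
        assert len(frame) == 4 * 11


class TestSteadySetSelection:
    REF = {"T4": 58.3, "G4": 46.7, "B4": 24.0, "P0": 50.0}

    def test_strong_repression_set_accepted(self, reference_spec):
        good = Pu1Params(rho=(0.01, 5.0, 5.0, 0.5), f_P=10.0, gamma_P=2.0)
        assert select_steady_sets(reference_spec, [good], self.REF) == [good]

    def test_runaway_pu1_rejected(self, reference_spec):
        bad = Pu1Params(rho=(0.5, 1e-6, 1e-6, 1e-7), f_P=500.0, gamma_P=0.5)
        assert select_steady_sets(reference_spec, [bad], self.REF) == []

    def test_empty_input_gives_empty_output(self, reference_spec):
        assert select_steady_sets(reference_spec, [], self.REF) == []

    def test_missing_reference_key_rejected(self, reference_spec):
        with pytest.raises(ValueError):
            select_steady_sets(reference_spec, [], {"T4": 1.0})
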