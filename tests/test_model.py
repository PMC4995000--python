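"""ODE system: Notch signal, right-hand side, simulation, steady states."""

import numpy as np
import pytest

from tcommit.logic import get_configuration
from tcommit.model import (
    GENES,
    GeneState,
    ModelParameters,
    ModelSpec,
    NotchSignal,
    notch_signal,
    rhs,
    simulate,
    steady_state,
)
from tcommit.synthetic import etp_like_init


def _plain_spec(kappa=(0.5,), variant="8b", **overrides):
    params = dict(
        eta=(0.3, 0.02, 0.01, 0.01),
        delta=(0.2, 0.01, 0.01),
        kappa=kappa,
        f=(50.0, 60.0, 40.0, 80.0),
        gamma=(1.0, 1.2, 0.9, 1.5),
        rho=(0.05, 0.03, 0.03, 0.01),
    )
    params.update(overrides)
    return ModelSpec(
        logic=get_configuration(variant),
        params=ModelParameters(**params),
        notch=NotchSignal(n_max=1.0, alpha=0.5, t_half=1.0, floor=0.3),
    )


class TestNotchSignal:
    def test_midpoint_and_saturation(self):
        sig = NotchSignal(n_max=2.0, alpha=0.4, t_half=1.5, floor=0.5)
        assert notch_signal(1.5, sig) == pytest.approx((0.5 + 2.0) / 2)
        assert notch_signal(1e6, sig) == pytest.approx(2.0)
        t = np.linspace(-5, 10, 200)
        assert np.all(np.diff(sig.signal(t)) >= 0)
        assert np.all(sig.signal(t) >= 0.5) and np.all(sig.signal(t) <= 2.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NotchSignal(alpha=0.0)
        with pytest.raises(ValueError):
            NotchSignal(floor=2.0, n_max=1.0)

    @pytest.mark.parametrize("fold", [1.2, 2.0, 3.5])
    def test_from_fold_is_exact(self, fold):
        sig = NotchSignal.from_fold(fold=fold, alpha=0.6, t_half=1.8)
        assert sig.fold(0.0, 4.0) == pytest.approx(fold, rel=1e-9)


class TestRhs:
    def test_zero_state_algebra(self):
        spec = _plain_spec(variant="1a", kappa=(0.4, 0.1, 0.1))
        nu = 0.7
        rates = rhs(GeneState(0, 0, 0, 0), 0.0, spec, nu=nu)
        assert rates[3] == 0.0  # PU.1 has no regulated positive input
        k1nu = 0.4 * nu
        assert rates[2] == pytest.approx(spec.params.f[2] * k1nu / (1 + k1nu))

    def test_pu1_repression_lowers_tcf1_rate(self):
        base = _plain_spec(eta=(0.3, 0.02, 0.01, 0.0))
        rep = _plain_spec(eta=(0.3, 0.02, 0.01, 0.5))
        state = GeneState(5.0, 5.0, 0.0, 10.0)
        assert rhs(state, 0.0, rep, nu=1.0)[0] < rhs(state, 0.0, base, nu=1.0)[0]

    def test_negative_state_rejected(self):
        spec = _plain_spec()
        with pytest.raises(ValueError):
            rhs((-1.0, 0, 0, 0), 0.0, spec)

    def test_committed_state_is_stationary_for_winning_model(self, winning_specs):
        spec = winning_specs["6d"]
        c = spec.ceilings()
        state, stable = steady_state(
            spec, 1.0, GeneState(0.9 * c["T"], 0.9 * c["G"], 0.9 * c["B"], 0.0),
            clamps={"P": 0.0},
        )
        rates = rhs(state, 0.0, spec, nu=1.0)
        scale = np.array([spec.params.f[i] for i in range(3)])
        assert np.all(np.abs(rates[:3]) / scale < 1e-8)
        assert stable


class TestSimulate:
    def test_pure_decay_closed_form(self):
        spec = _plain_spec(eta=(0, 0, 0, 0), delta=(0, 0, 0), kappa=(0.0,),
                           rho=(0, 0, 0, 0))
        t = np.linspace(0, 3, 7)
        traj = simulate(spec, GeneState(10.0, 0, 0, 0), t)
        assert traj["T"] == pytest.approx(10.0 * np.exp(-spec.params.gamma[0] * t),
                                          rel=1e-6)

    def test_full_clamping_returns_the_clamps(self):
        spec = _plain_spec()
        t = np.linspace(0, 4, 9)
        clamps = {"T": 3.0, "G": 1.5, "B": 0.25, "P": 7.0}
        traj = simulate(spec, GeneState(0, 0, 0, 0), t, clamps=clamps)
        for g, v in clamps.items():
            assert np.all(traj[g] == v)

    def test_nonnegative_and_bounded_trajectories(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            spec = _plain_spec(
                variant="6d", kappa=(rng.uniform(0, 1), rng.uniform(0, 1)),
                eta=tuple(rng.uniform(0, 0.5, 4)),
                delta=tuple(rng.uniform(0, 0.5, 3)),
                rho=tuple(rng.uniform(0, 0.1, 4)),
            )
            init = etp_like_init(spec)
            traj = simulate(spec, init, np.linspace(0, 6, 25))
            assert np.all(traj.values >= 0)
            for i, g in enumerate(GENES):
                assert np.all(traj.values[i] <= spec.params.ceiling(g) * (1 + 1e-6)
                              + init[i])

    def test_bad_grid_rejected(self):
        spec = _plain_spec()
        with pytest.raises(ValueError):
            simulate(spec, GeneState(0, 0, 0, 0), [0.0, 0.0, 1.0])

    def test_tidy_frame_round_trip(self):
        spec = _plain_spec()
        traj = simulate(spec, etp_like_init(spec), np.linspace(0, 2, 5))
        from tcommit.model import Trajectory

        back = Trajectory.from_frame(traj.to_frame())
        assert np.allclose(back.values, traj.values)


class TestSteadyState:
    def test_zero_production_gives_stable_origin(self):
        spec = _plain_spec(eta=(0, 0, 0, 0), delta=(0, 0, 0), kappa=(0.0,),
                           rho=(0, 0, 0, 0))
        state, stable = steady_state(spec, 1.0, GeneState(5, 5, 5, 5))
        assert np.allclose(state, 0.0, atol=1e-8)
        assert stable

    def test_pu1_zero_is_invariant(self):
        spec = _plain_spec()
        for level in (0.0, 0.5, 1.0):
            state, _ = steady_state(spec, level, GeneState(1, 1, 1, 0))
            assert state.P == 0.0

    def test_simulation_agrees_with_root_finding(self, reference_spec):
        spec = reference_spec
        init = etp_like_init(spec)
        # long integration at frozen full Notch
        traj = simulate(spec, init, np.linspace(0, 200, 60), nu=1.0)
        state, stable = steady_state(spec, spec.notch.n_max, init)
        for i in range(4):
            denom = max(abs(state[i]), 1e-12)
            assert abs(traj.values[i, -1] - state[i]) / denom < 1e-6
        assert stable

    def test_bcl11b_high_branch_persists_at_zero_notch(self, winning_specs):
        spec = winning_specs["6d"]
        c = spec.ceilings()
        committed, _ = steady_state(
            spec, 1.0, GeneState(0.9 * c["T"], 0.9 * c["G"], 0.9 * c["B"], 0.0),
            clamps={"P": 0.0},
        )
        state, _ = steady_state(
            spec, 0.0, GeneState(committed.T, committed.G, committed.B, 0.0),
            clamps={"P": 0.0},
        )
        assert state.B > 0.5 * committed.B

    def test_stability_flag_matches_perturb_and_integrate(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 20:
            spec = _plain_spec(
                variant="1a",
                kappa=tuple(rng.uniform(0.01, 1.0, 3)),
                eta=tuple(rng.uniform(0, 0.5, 4)),
                delta=tuple(rng.uniform(0, 0.5, 3)),
                rho=tuple(rng.uniform(0, 0.2, 4)),
                f=tuple(rng.uniform(20, 100, 4)),
                gamma=tuple(rng.uniform(0.5, 3.0, 4)),
            )
            init = GeneState(*rng.uniform(0, 20, 4))
            state, stable = steady_state(spec, 1.0, init)
            kicked = GeneState(*(max(v * 1.01, 1e-6) for v in state))
            traj = simulate(spec, kicked, np.linspace(0, 50, 10), nu=1.0)
            returned = all(
                abs(traj.values[i, -1] - state[i]) <= 1e-3 * max(abs(state[i]), 1e-6)
                for i in range(4)
            )
            assert returned == stable
            checked += 1
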