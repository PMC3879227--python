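"""Bifurcation structure of the shipped regimes: fold counts, oracle
agreement, switch classification, stress-pulse trapping, limit cycles."""

import numpy as np
import pytest

import hpaxis as h
from hpaxis.bifurcation import find_equilibrium

from oracle_branch import fold_abscissas_dense


@pytest.fixture(scope="module")
def hypo_branch(fixture_regimes):
    return h.continue_equilibria(fixture_regimes["hypo_switch"], (0.0, 1.0),
                                 max_points=1500)


@pytest.fixture(scope="module")
def hyper_branch(fixture_regimes):
    return h.continue_equilibria(fixture_regimes["hyper_switch"], (0.0, 1.0),
                                 max_points=1500)


class TestHypoSwitch:
    def test_two_limit_points_with_three_coexisting_equilibria(
        self, fixture_regimes, hypo_branch
    ):
        """Between the fold abscissas three equilibria coexist, two of
        them stable -- the bistable window of the switch."""
        assert len(hypo_branch.limit_points) == 2
        S1, S2 = hypo_branch.lp_abscissas
        S_mid = 0.5 * (S1 + S2)
        in_window = (hypo_branch.stress > min(S1, S2) + 1e-3) & (
            hypo_branch.stress < max(S1, S2) - 1e-3
        )
        # the branch passes through the window three times
        crossings = np.sum(np.abs(np.diff(in_window.astype(int))))
        assert crossings >= 4
        stable_in = hypo_branch.stable[in_window]
        assert stable_in.any() and (~stable_in).any()

    def test_classification_irreversible_hypo(self, hypo_branch):
        cls = h.classify_switch(hypo_branch, basal_stress=0.1)
        assert cls.kind == "irreversible_bistable"
        assert cls.orientation == "hypo"
        assert cls.S2 < 0.1 < cls.S1

    def test_fold_abscissas_match_dense_grid_oracle(
        self, fixture_regimes, hypo_branch
    ):
        """Continuation fold abscissas agree with an independent
        dense-grid multi-start equilibrium-counting oracle to 1e-4."""
        folds = sorted(fold_abscissas_dense(
            fixture_regimes["hypo_switch"], (0.0, 1.0), tol=1e-5))
        got = sorted(hypo_branch.lp_abscissas)
        assert len(folds) == 2
        for a, b in zip(folds, got):
            assert abs(a - b) < 1e-4

    def test_limit_point_eigenvalue_near_zero(self, fixture_regimes, hypo_branch):
        for S_lp, x_lp in hypo_branch.limit_points:
            eigs = np.linalg.eigvals(
                h.jacobian(x_lp, fixture_regimes["hypo_switch"], S_lp))
            assert np.min(np.abs(eigs.real)) < 1e-6

    def test_stability_flips_only_at_limit_points(self, hypo_branch):
        flips = np.where(np.diff(hypo_branch.stable.astype(int)) != 0)[0]
        assert len(flips) == 2
        lp_S = sorted(hypo_branch.lp_abscissas)
        for i in flips:
            S_flip = 0.5 * (hypo_branch.stress[i] + hypo_branch.stress[i + 1])
            assert min(abs(S_flip - s) for s in lp_S) < 0.02

    def test_pulse_traps_low_cortisol_branch(self, fixture_regimes, hypo_branch):
        """A temporary stressor above LP1 leaves the axis at the low-
        cortisol equilibrium of the branch (hypocortisolism)."""
        p = fixture_regimes["hypo_switch"]
        cls = h.classify_switch(hypo_branch, 0.1)
        healthy = hypo_branch.basal_state(0.1)
        proto = h.StressProtocol(
            baseline=0.1, pulses=((200.0, 1800.0, min(1.0, cls.S1 * 1.6)),))
        traj, post = h.simulate_stress_response(p, proto, 4000.0,
                                                initial=healthy)
        assert post[0] < 0.8 * traj.states[0, 0]
        # the trapped state is the alternative stable equilibrium
        eq = find_equilibrium(p, 0.1, guess=post)
        assert eq.stable
        assert eq.state[0] == pytest.approx(post[0], rel=1e-3)


class TestHyperSwitch:
    def test_classification_irreversible_hyper(self, hyper_branch):
        """Inverted branch alignment: the state reached past LP1 carries
        the HIGHER cortisol level, and LP2 sits below basal stress."""
        cls = h.classify_switch(hyper_branch, basal_stress=0.1)
        assert cls.kind == "irreversible_bistable"
        assert cls.orientation == "hyper"
        assert cls.S2 < 0.1 < cls.S1

    def test_limit_points_carry_zero_eigenvalue(self, fixture_regimes,
                                                hyper_branch):
        assert len(hyper_branch.limit_points) == 2
        for S_lp, x_lp in hyper_branch.limit_points:
            eigs = np.linalg.eigvals(
                h.jacobian(x_lp, fixture_regimes["hyper_switch"], S_lp))
            assert np.min(np.abs(eigs.real)) < 1e-6

    def test_pulse_traps_high_cortisol_branch(self, fixture_regimes,
                                              hyper_branch):
        p = fixture_regimes["hyper_switch"]
        cls = h.classify_switch(hyper_branch, 0.1)
        healthy = hyper_branch.basal_state(0.1)
        proto = h.StressProtocol(
            baseline=0.1, pulses=((200.0, 1800.0, min(1.0, cls.S1 * 1.6)),))
        traj, post = h.simulate_stress_response(p, proto, 4000.0,
                                                initial=healthy)
        assert post[0] > 1.1 * traj.states[0, 0]


class TestOscillatoryRegime:
    def test_hopf_points_located(self, fixture_regimes):
        br = h.continue_equilibria(fixture_regimes["oscillatory"], (0.0, 1.0),
                                   max_points=1500)
        assert len(br.hopf_points) >= 1
        for S_h, x_h, omega in br.hopf_points:
            eigs = np.linalg.eigvals(
                h.jacobian(x_h, fixture_regimes["oscillatory"], S_h))
            cplx = eigs[np.abs(eigs.imag) > 1e-4]
            assert np.min(np.abs(cplx.real)) < 1e-6
            assert omega > 1e-4

    def test_sustained_cycle_with_cascade_phase_order(self, fixture_regimes):
        """Within one period the hormone maxima follow the release
        cascade: CRH before ACTH before cortisol."""
        lc = h.limit_cycle(fixture_regimes["oscillatory"], 0.25,
                           t_transient=6000.0, t_observe=6000.0, n_out=4001)
        assert lc["sustained"]
        assert lc["phase_order"] == ("CRH", "ACTH_ex", "COR_ex")
        assert lc["period"] > 10.0

    def test_period_stable_under_horizon_doubling(self, fixture_regimes):
        p = fixture_regimes["oscillatory"]
        lc1 = h.limit_cycle(p, 0.25, t_transient=4000.0, t_observe=3000.0,
                            n_out=3001)
        lc2 = h.limit_cycle(p, 0.25, t_transient=4000.0, t_observe=6000.0,
                            n_out=6001)
        assert lc1["sustained"] and lc2["sustained"]
        assert lc1["period"] == pytest.approx(lc2["period"], rel=0.01)
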