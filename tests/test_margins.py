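"""eMOS state margins, experimental margin estimators, exercise targets."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bobkit.geometry import BalanceCategory, boundary_margins, classify_state
from bobkit.lip import UNDEFINED, LinearBounds, LipParams, lip_bounds, xcom
from bobkit.margins import (
    BoundSide,
    TargetCategory,
    Trajectory,
    UnsupportedCategoryError,
    emos,
    emos_series,
    experimental_reachable_margin,
    experimental_viable_margin,
    make_targets,
)
from bobkit.models import COMState

from test_geometry import make_bob


LIP_BOUNDS = lip_bounds(LipParams(fl=0.23, ybar=1.12), nondimensional=True)


def traj_from_arrays(t, x, xdot, nondim=True):
    return Trajectory(t=t, x=x, y=np.ones_like(np.asarray(t, dtype=float)),
                      xdot=xdot, ydot=np.zeros_like(np.asarray(t, dtype=float)),
                      stance_intact=np.ones(len(t), dtype=bool),
                      nondimensional=nondim)


class TestEmos:
    def test_state_on_lower_bound(self):
        s = COMState(0.3, 1.0, -0.3, 0.0)  # xdot = -x: on the lower line
        r = emos(s, LIP_BOUNDS)
        assert r.e_lower == pytest.approx(0.0, abs=1e-12)
        assert r.critical == pytest.approx(0.0, abs=1e-12)
        assert r.critical_side is BoundSide.LOWER

    def test_lip_reduces_to_xcom_margins(self):
        """On LIP bounds the two eMOS components are the XCoM distances to
        the support edges: e_lower = XCoM*, e_upper = 1 - XCoM*."""
        s = COMState(0.3, 1.0, 0.2, 0.0)
        r = emos(s, LIP_BOUNDS)
        xc = xcom(0.3, 0.2, 1.0)
        assert r.e_lower == pytest.approx(xc)       # = 0.5
        assert r.e_upper == pytest.approx(1.0 - xc)  # = 0.5

    def test_interior_states_have_margins_in_unit_interval(self, rng):
        """For balanced LIP states each per-bound margin lies in (0, 1)."""
        for _ in range(500):
            x = rng.uniform(-0.5, 1.5)
            lo, hi = -x, -x + 1
            xd = rng.uniform(lo + 1e-6, hi - 1e-6)
            r = emos(COMState(x, 1.0, xd, 0.0), LIP_BOUNDS)
            assert 0 < r.e_lower < 1
            assert 0 < r.e_upper < 1

    @settings(derandomize=True, max_examples=300)
    @given(x=st.floats(-1, 2), xd=st.floats(-2, 2))
    def test_lip_equivalence_property(self, x, xd):
        """emos on LIP bounds equals min(XCoM*, 1 - XCoM*) in magnitude of
        the critical component, to machine precision."""
        r = emos(COMState(x, 1.0, xd, 0.0), LIP_BOUNDS)
        xc = x + xd  # omega* = 1
        expected = xc if abs(xc) <= abs(1 - xc) else 1 - xc
        assert r.critical == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_tie_breaks_to_lower(self):
        r = emos(COMState(0.25, 1.0, 0.25, 0.0), LIP_BOUNDS)  # XCoM = 0.5
        assert r.critical_side is BoundSide.LOWER

    def test_degenerate_bounds_rejected(self):
        flat = LinearBounds(lower=(0.0, -1.0), upper=(0.0, 1.0))
        with pytest.raises(ValueError):
            emos(COMState(0.0, 1.0, 0.0, 0.0), flat)

    def test_extrapolation_flagged_outside_domain(self):
        b = LinearBounds(lower=(-1.0, 0.0), upper=(-1.0, 1.0), domain=(0.0, 1.0))
        assert emos(COMState(2.0, 1.0, -1.0, 0.0), b).extrapolated
        assert not emos(COMState(0.5, 1.0, 0.0, 0.0), b).extrapolated


class TestEmosSeries:
    def test_constant_state_constant_series(self):
        t = np.linspace(0, 1, 20)
        traj = traj_from_arrays(t, np.full(20, 0.4), np.zeros(20))
        series = emos_series(traj, LIP_BOUNDS)
        crit = series.critical
        assert np.allclose(crit, crit[0])

    def test_posterior_recovery_switches_sides(self):
        """A recovery from a posterior perturbation starts nearer the lower
        bound and ends nearer the upper bound."""
        # XCoM rises from near 0 (posterior edge) toward the anterior half
        t = np.linspace(0, 1.5, 60)
        xc = 0.1 + 0.75 * (1 - np.exp(-3 * t))
        x = xc - 0.1  # arbitrary split between position and velocity
        xd = xc - x
        traj = traj_from_arrays(t, x, xd)
        series = emos_series(traj, LIP_BOUNDS)
        sides = [r.critical_side for r in series]
        assert sides[0] is BoundSide.LOWER
        assert sides[-1] is BoundSide.UPPER
        assert 0 < series.frac_lower < 1
        assert series.frac_lower + series.frac_upper == pytest.approx(1.0)

    def test_normalization_round_trip_invariance(self):
        fl, omega = 0.23, np.sqrt(9.81 / 1.12)
        t = np.linspace(0, 1, 30)
        x = 0.3 + 0.2 * np.sin(t)
        xd = 0.2 * np.cos(t)
        traj = traj_from_arrays(t, x, xd)
        series = emos_series(traj, LIP_BOUNDS)
        # nondimensional -> dimensional -> nondimensional
        traj_dim = traj_from_arrays(t, x * fl, xd * fl * omega, nondim=False)
        traj_back = traj_from_arrays(t, traj_dim.x / fl, traj_dim.xdot / (fl * omega))
        series2 = emos_series(traj_back, LIP_BOUNDS)
        assert np.allclose(series.critical, series2.critical, atol=1e-14)

    def test_mismatched_normalization_rejected(self):
        t = np.linspace(0, 1, 10)
        traj = traj_from_arrays(t, np.zeros(10), np.zeros(10), nondim=False)
        with pytest.raises(ValueError):
            emos_series(traj, LIP_BOUNDS)


class TestExperimentalReachableMargin:
    def test_sway_beyond_edge(self):
        """Sinusoidal sway peaking at x* = 1.1 before reversing gives an
        anterior margin of 0.1."""
        t = np.linspace(0, 2, 200)
        x = 1.1 * np.sin(np.pi * t / 2)
        xd = 1.1 * np.pi / 2 * np.cos(np.pi * t / 2)
        m = experimental_reachable_margin(traj_from_arrays(t, x, xd), "ANT")
        assert m == pytest.approx(0.1, abs=1e-3)

    def test_inversion_inside_support_is_negative(self):
        t = np.linspace(0, 2, 200)
        x = 0.8 * np.sin(np.pi * t / 2)
        xd = 0.8 * np.pi / 2 * np.cos(np.pi * t / 2)
        m = experimental_reachable_margin(traj_from_arrays(t, x, xd), "ANT")
        assert m == pytest.approx(-0.2, abs=1e-3)

    def test_noise_robust_within_tolerance(self, rng):
        """With seeded noise of sigma=0.005 the detected margin stays within
        0.01 of the noise-free value."""
        t = np.linspace(0, 2, 400)
        x = 1.05 * np.sin(np.pi * t / 2)
        xd = 1.05 * np.pi / 2 * np.cos(np.pi * t / 2)
        clean = experimental_reachable_margin(traj_from_arrays(t, x, xd), "ANT")
        noisy = traj_from_arrays(t, x + rng.normal(0, 0.005, t.size),
                                 xd + rng.normal(0, 0.005, t.size))
        m = experimental_reachable_margin(noisy, "ANT")
        assert abs(m - clean) < 0.01

    def test_no_inversion_undefined(self):
        t = np.linspace(0, 1, 50)
        traj = traj_from_arrays(t, 0.1 + 0.5 * t, np.full(50, 0.5))
        assert experimental_reachable_margin(traj, "ANT") is UNDEFINED

    def test_posterior_direction(self):
        t = np.linspace(0, 2, 200)
        x = -0.3 * np.sin(np.pi * t / 2)
        xd = -0.3 * np.pi / 2 * np.cos(np.pi * t / 2)
        m = experimental_reachable_margin(traj_from_arrays(t, x, xd), "POS")
        assert m == pytest.approx(0.3, abs=1e-3)


class TestExperimentalViableMargin:
    def test_extreme_successful_trial(self):
        """A trial set whose most extreme successful initial position is
        x* = -0.519 yields a posterior margin of 0.519."""
        trials = [
            (COMState(-0.519, 1.0, 0.9, 0.0), True),
            (COMState(-0.30, 1.0, 0.5, 0.0), True),
            (COMState(-0.65, 1.0, 1.2, 0.0), False),
            (COMState(0.10, 1.0, 0.0, 0.0), True),
        ]
        assert experimental_viable_margin(trials, "POS") == pytest.approx(0.519)

    def test_all_failed_undefined(self):
        trials = [(COMState(-0.4, 1.0, 0.8, 0.0), False)]
        assert experimental_viable_margin(trials, "POS") is UNDEFINED

    def test_single_success(self):
        trials = [(COMState(-0.1, 1.0, 0.2, 0.0), True)]
        assert experimental_viable_margin(trials, "POS") == pytest.approx(0.1)

    def test_empty_trial_set_rejected(self):
        with pytest.raises(ValueError):
            experimental_viable_margin([], "POS")


@pytest.fixture(scope="module")
def fixture_bob():
    """A synthetic two-link-foot-like balanced region with all partitions."""
    x = np.linspace(-0.591, 1.808, 25)
    return make_bob(x, -1.02 * x - 0.29, -1.19 * x + 1.61,
                    domain=(-0.591, 1.808))


class TestMakeTargets:
    def test_category_a_progression(self, fixture_bob):
        m = boundary_margins(fixture_bob)
        targets = make_targets(fixture_bob, m, TargetCategory.A_REACHABLE, 3, "POS")
        assert len(targets) == 3
        xs = [t.target_state.x for t in targets]
        assert xs[0] > xs[1] > xs[2]  # monotonically approaching the margin
        for t in targets:
            assert t.target_state.x < 0  # outside the footprint
            assert classify_state(t.target_state, fixture_bob, m) \
                is BalanceCategory.REACHABLE

    def test_category_b_in_viable_partition(self, fixture_bob):
        m = boundary_margins(fixture_bob)
        targets = make_targets(fixture_bob, m, TargetCategory.B_VIABLE, 3, "POS")
        for t in targets:
            assert classify_state(t.target_state, fixture_bob, m) \
                is BalanceCategory.VIABLE

    def test_category_c_zero_emos_on_boundary(self, fixture_bob):
        from bobkit.geometry import fit_bounds
        m = boundary_margins(fixture_bob)
        targets = make_targets(fixture_bob, m, TargetCategory.C_VIAPOINT, 1,
                               "POS", emos_levels=[0.0])
        bounds = fit_bounds(fixture_bob)
        r = emos(targets[0].target_state, bounds)
        assert r.critical == pytest.approx(0.0, abs=1e-9)

    def test_category_b_on_lip_unsupported(self):
        x = np.linspace(0, 1, 11)
        lip_bob = make_bob(x, -x, -x + 1, domain="unbounded")
        m = boundary_margins(lip_bob)
        with pytest.raises(UnsupportedCategoryError):
            make_targets(lip_bob, m, TargetCategory.B_VIABLE, 2, "POS")


class TestTrajectoryValidation:
    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            traj_from_arrays([0.0], [0.0], [0.0])

    def test_strictly_increasing_times(self):
        with pytest.raises(ValueError):
            traj_from_arrays([0.0, 0.0, 1.0], np.zeros(3), np.zeros(3))
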