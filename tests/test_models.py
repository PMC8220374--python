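"""Mechanics of the planar chain models: kinematics, contact inverse
dynamics, constraint reporting."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from bobkit.models import (
    BodyConfiguration,
    ConfigurationError,
    ContactMode,
    StanceSpec,
    UnsupportedModelError,
    com_state,
    constraint_violations,
    dof4_model,
    dof5_model,
    inverse_dynamics_contact,
    lip_model,
    toy_pendulum_flywheel,
)

from _oracles import per_link_com


class TestComState:
    def test_upright_reference_height(self, m4):
        """The upright posture places the whole-body COM at the standing
        height the parameter set was scaled to (1.12 m)."""
        cfg = BodyConfiguration(np.zeros(4), np.zeros(4))
        cs = com_state(m4, cfg)
        assert cs.y == pytest.approx(1.12, abs=1e-12)
        assert cs.xdot == 0.0 and cs.ydot == 0.0

    def test_zero_velocity_configuration(self, m4, rng):
        q = rng.normal(0, 0.3, 4)
        cs = com_state(m4, BodyConfiguration(q, np.zeros(4)))
        assert cs.xdot == 0.0 and cs.ydot == 0.0

    def test_matches_per_link_oracle(self, m4, rng):
        """COM equals an independently coded mass-weighted per-link sum, and
        the COM velocity matches a finite-difference derivative."""
        chain = m4.chain()
        q = rng.normal(0, 0.4, 4)
        qd = rng.normal(0, 0.8, 4)
        num, vnum = per_link_com(chain.base, chain.offsets, chain.attach_d,
                                 chain.com_d, chain.masses, q, qd)
        mtot = chain.masses.sum() + sum(m for m, *_ in chain.static_masses)
        for ms, xs, ys in chain.static_masses:
            num = num + ms * np.array([xs, ys])
        cs = com_state(m4, BodyConfiguration(q, qd))
        assert np.allclose([cs.x, cs.y], num / mtot, atol=1e-12)
        assert np.allclose([cs.xdot, cs.ydot], vnum / mtot, atol=1e-12)
        # finite-difference check of the velocity
        eps = 1e-7
        cs2 = com_state(m4, BodyConfiguration(q + eps * qd, qd))
        fd = ((cs2.x - cs.x) / eps, (cs2.y - cs.y) / eps)
        assert np.allclose(fd, [cs.xdot, cs.ydot], atol=1e-5)

    def test_dimension_mismatch_raises(self, m4):
        with pytest.raises(ConfigurationError):
            com_state(m4, BodyConfiguration(np.zeros(5), np.zeros(5)))


class TestInverseDynamics:
    def test_static_equilibrium_wrench(self, m4, ref_params):
        """At rest the vertical reaction equals total weight and the COP
        sits under the COM."""
        cfg = BodyConfiguration(np.zeros(4), np.zeros(4))
        w = inverse_dynamics_contact(m4, cfg, np.zeros(4), ContactMode.FLAT)
        assert w.grf_vertical == pytest.approx(ref_params.total_mass * 9.81, rel=1e-12)
        assert w.grf_horizontal == pytest.approx(0.0, abs=1e-9)
        cs = com_state(m4, cfg)
        assert w.cop_x == pytest.approx(cs.x, abs=1e-12)
        assert not w.contact_separation

    def test_single_link_statics_oracle(self, toy):
        """Prescribing an ankle torque on the single-pendulum reduction
        shifts the COP by tau/grf from the ankle (hand-derived statics)."""
        tau = 20.0
        qdd = toy.chain.forward_dynamics(np.zeros(2), np.zeros(2), [tau, 0.0])
        _, grf, cop = toy.chain.inverse_dynamics(
            np.zeros((1, 2)), np.zeros((1, 2)), qdd[None, :])
        assert abs(cop[0] - toy.chain.base[0]) == pytest.approx(
            tau / grf[0, 1], rel=1e-9)

    def test_gravity_free_identity(self, m4, rng):
        q = rng.normal(0, 0.3, 4)
        chain = m4.chain()
        tau, grf, cop = chain.inverse_dynamics(q[None, :], np.zeros((1, 4)),
                                               np.zeros((1, 4)), g=0.0)
        assert np.allclose(tau, 0.0, atol=1e-12)
        assert np.allclose(grf, 0.0, atol=1e-12)

    def test_lip_unsupported(self, lip_ref):
        with pytest.raises(UnsupportedModelError):
            inverse_dynamics_contact(lip_ref, BodyConfiguration([0.1], [0.0]),
                                     [0.0], ContactMode.FLAT)

    def test_locked_metatarsal_reproduces_rigid_foot(self, m4, m5, rng):
        """A 5-DOF model with the foot coordinate pinned at zero produces the
        4-DOF inverse-dynamics torques on the shared joints."""
        q = rng.normal(0, 0.3, 4)
        qd = rng.normal(0, 0.5, 4)
        qdd = rng.normal(0, 1.0, 4)
        w4 = inverse_dynamics_contact(m4, BodyConfiguration(q, qd), qdd,
                                      ContactMode.FLAT)
        z = np.zeros(1)
        w5 = inverse_dynamics_contact(
            m5, BodyConfiguration(np.r_[z, q], np.r_[z, qd]), np.r_[z, qdd],
            ContactMode.FLAT)
        assert np.allclose(w5.torques[1:], w4.torques, atol=1e-8)
        assert w5.cop_x == pytest.approx(w4.cop_x, abs=1e-8)

    def test_pivot_modes_report_pivot_cop(self, m5):
        cfg = BodyConfiguration(np.array([-0.1, 0, 0, 0, 0]), np.zeros(5))
        w = inverse_dynamics_contact(m5, cfg, np.zeros(5), ContactMode.HEEL_PIVOT)
        assert w.cop_x == 0.0
        cfg_t = BodyConfiguration(np.array([0.1, 0, 0, 0, 0]), np.zeros(5))
        wt = inverse_dynamics_contact(m5, cfg_t, np.zeros(5), ContactMode.TOE_PIVOT)
        assert wt.cop_x == pytest.approx(m5.params.heel_to_metatarsal)

    def test_energy_conservation_free_pendulum(self, toy):
        """Torque-free simulation conserves mechanical energy to < 1e-6
        relative over one second."""
        chain = toy.chain

        def f(t, s):
            qdd = chain.forward_dynamics(s[:2], s[2:], np.zeros(2))
            return np.concatenate([s[2:], qdd])

        sol = solve_ivp(f, (0, 1.0), [0.3, 0.0, 0.0, 1.0],
                        rtol=1e-10, atol=1e-12)

        def energy(s):
            m1, l = chain.masses[0], chain.com_d[0]
            return (0.5 * m1 * (l * s[2]) ** 2
                    + 0.5 * chain.inertias[1] * (s[2] + s[3]) ** 2
                    + m1 * 9.81 * l * np.cos(s[0]))

        e0, e1 = energy(sol.y[:, 0]), energy(sol.y[:, -1])
        assert abs(e1 - e0) / abs(e0) < 1e-6


class TestConstraintViolations:
    def test_static_upright_clean(self, m4):
        cfg = BodyConfiguration(np.zeros(4), np.zeros(4))
        w = inverse_dynamics_contact(m4, cfg, np.zeros(4), ContactMode.FLAT)
        report = constraint_violations(m4, StanceSpec((0.0, 0.23)), cfg, w)
        assert report.ok

    def test_cop_exceedance_magnitude(self, m4):
        import dataclasses
        cfg = BodyConfiguration(np.zeros(4), np.zeros(4))
        w = inverse_dynamics_contact(m4, cfg, np.zeros(4), ContactMode.FLAT)
        w = dataclasses.replace(w, cop_x=0.23 + 0.01)
        report = constraint_violations(m4, StanceSpec((0.0, 0.23)), cfg, w)
        viol = {v.name: v.magnitude for v in report}
        assert viol["cop_out_of_support"] == pytest.approx(0.01)

    def test_torque_exceedance_magnitude(self, m4):
        import dataclasses
        cfg = BodyConfiguration(np.zeros(4), np.zeros(4))
        w = inverse_dynamics_contact(m4, cfg, np.zeros(4), ContactMode.FLAT)
        torques = w.torques.copy()
        torques[1] = m4.params.joint_torque_limits[1, 1] + 5.0
        w = dataclasses.replace(w, torques=torques)
        report = constraint_violations(m4, StanceSpec((0.0, 0.23)), cfg, w)
        viol = {v.name: v.magnitude for v in report}
        assert viol["torque_knee_max"] == pytest.approx(5.0)


class TestModelConstruction:
    def test_lip_exposes_only_scalars(self):
        m = lip_model(fl=0.23, ybar=1.12)
        assert m.params is None and m.dof_count == 1
        assert m.omega == pytest.approx(np.sqrt(9.81 / 1.12))

    def test_dof_count_consistency(self, ref_params):
        assert dof4_model(ref_params).dof_count == 4
        assert dof5_model(ref_params).dof_count == 5

    def test_stance_requires_flat(self):
        with pytest.raises(ValueError):
            StanceSpec((0.0, 0.23), frozenset({ContactMode.HEEL_PIVOT}))

    def test_foot_geometry_must_sum(self, ref_params):
        import dataclasses
        with pytest.raises(ValueError):
            dataclasses.replace(ref_params, foot_geometry=(0.1, 0.1, 0.1))
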