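import itertools

import numpy as np
import pytest

from wingkin.actuation import (ActuationConfig, RopePoint,
                               default_actuation_config, motor_force,
                               rope_length, spring_force, sweep_endpoints)
from wingkin.geometry import rotation_about_line
from wingkin.mechanism import mechanism_forward


@pytest.fixture(scope="module")
def act_config(mech_config):
    return default_actuation_config(mech_config)


@pytest.fixture(scope="module")
def flexed(mech_config):
    return mechanism_forward(mech_config, 20.0)


class TestRopeLength:
    def test_coincident_points_have_zero_length(self, flexed):
        p = RopePoint("base", [1.0, 2.0, 3.0])
        assert rope_length(flexed, [p, p]) == 0.0

    def test_three_four_five(self, flexed):
        path = [RopePoint("base", [0, 0, 0]), RopePoint("base", [3.0, 4.0, 0.0])]
        assert rope_length(flexed, path) == pytest.approx(5.0)

    def test_multi_segment_sum(self, flexed):
        path = [RopePoint("base", [0, 0, 0]), RopePoint("base", [3, 4, 0]),
                RopePoint("base", [3, 4, 12.0])]
        assert rope_length(flexed, path) == pytest.approx(17.0)

    def test_unknown_bone_rejected(self, flexed):
        with pytest.raises(ValueError, match="unknown bone"):
            rope_length(flexed, [RopePoint("femur", [0, 0, 0]),
                                 RopePoint("base", [1, 0, 0])])

    def test_invariant_under_global_pitch_of_the_assembly(self, mech_config, act_config):
        # joint 5 rotates every bone together: bone-attached rope lengths
        # cannot change
        bu, bh = act_config.candidates["BU"][1], act_config.candidates["BH"][1]
        s0 = mechanism_forward(mech_config, 18.0, theta5=0.0)
        s1 = mechanism_forward(mech_config, 18.0, theta5=25.0)
        assert rope_length(s0, [bh, bu]) == pytest.approx(
            rope_length(s1, [bh, bu]), abs=1e-9)


class TestSpringLaw:
    def test_preload_at_zero_stretch(self, act_config):
        assert spring_force(0.0, act_config) == pytest.approx(4.5)

    def test_unit_stretch(self, act_config):
        assert spring_force(1.0, act_config) == pytest.approx(4.687)

    def test_negative_stretch_rejected(self, act_config):
        with pytest.raises(ValueError, match="slack"):
            spring_force(-0.1, act_config)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="stiffness"):
            ActuationConfig(candidates={s: (RopePoint("base", np.zeros(3)),) * 3
                                        for s in ("BU", "BH", "TU", "TH")},
                            spring_stiffness_n_mm=-1.0)


class TestMotorForce:
    def test_identical_rope_geometry_balances_spring(self, mech_config, act_config,
                                                     flexed):
        bu = act_config.candidates["BU"][1]
        tu = act_config.candidates["TU"][1]
        bh = act_config.candidates["BH"][0]
        rope = [bh, tu]
        f = motor_force(mech_config, flexed, rope, rope, act_config)
        l_ref = rope_length(mechanism_forward(mech_config, 0.0), rope)
        stretch = max(rope_length(flexed, rope) - l_ref, 0.0)
        assert f == pytest.approx(spring_force(stretch, act_config), rel=1e-9)

    def test_affine_in_spring_preload(self, mech_config, act_config, flexed):
        rope1 = [act_config.candidates["BH"][1], act_config.candidates["BU"][1]]
        rope2 = [act_config.candidates["TU"][1], act_config.candidates["TH"][1]]
        import dataclasses
        doubled = dataclasses.replace(act_config, spring_preload_n=9.0)
        f1 = motor_force(mech_config, flexed, rope1, rope2, act_config)
        f2 = motor_force(mech_config, flexed, rope1, rope2, doubled)
        l_ref = rope_length(mechanism_forward(mech_config, 0.0), rope2)
        stretch = rope_length(flexed, rope2) - l_ref
        ratio = (9.0 + 0.187 * stretch) / (4.5 + 0.187 * stretch)
        assert f2 / f1 == pytest.approx(ratio, rel=1e-6)

    def test_matches_analytic_lever_arm_oracle(self, mech_config, act_config):
        # closed form: for a rope from fixed P to a point Q riding the ulna,
        # dL/dtheta1 = (pi/180) * (a x (Q - c)) . (Q - P) / |Q - P|
        state = mechanism_forward(mech_config, 20.0)
        j1 = mech_config.joints[1]
        rope1 = [act_config.candidates["BH"][1], act_config.candidates["BU"][2]]
        rope2 = [act_config.candidates["TU"][0], act_config.candidates["TH"][1]]

        def analytic_dl(p_fixed, q_ref):
            q = state.transforms["ulna"].apply(q_ref)
            p = p_fixed
            v = q - p
            return np.radians(1.0) * np.cross(j1.u_b3, q - j1.center) @ v / np.linalg.norm(v)

        dl1 = analytic_dl(rope1[0].point, rope1[1].point)
        dl2 = analytic_dl(rope2[1].point, rope2[0].point)
        l2_ref = rope_length(mechanism_forward(mech_config, 0.0), rope2)
        stretch = rope_length(state, rope2) - l2_ref
        expected = spring_force(max(stretch, 0.0), act_config) * abs(dl2) / abs(dl1)
        got = motor_force(mech_config, state, rope1, rope2, act_config)
        assert got == pytest.approx(expected, abs=1e-6)

    def test_energy_consistency_over_the_stroke(self, mech_config, act_config):
        # quasi-static, frictionless: motor work equals the spring energy gain
        rope1 = [act_config.candidates["BH"][1], act_config.candidates["BU"][1]]
        rope2 = [act_config.candidates["TU"][1], act_config.candidates["TH"][1]]
        thetas = np.linspace(0.0, 37.18, 200)
        states = []
        warm = None
        for th in thetas:
            warm = mechanism_forward(mech_config, th, warm_state=warm)
            states.append(warm)
        l1 = np.array([rope_length(s, rope1) for s in states])
        l2 = np.array([rope_length(s, rope2) for s in states])
        k, f0 = act_config.spring_stiffness_n_mm, act_config.spring_preload_n
        f_spring = f0 + k * (l2 - l2[0])
        # motor force from virtual work at segment midpoints
        fm = 0.5 * (f_spring[1:] + f_spring[:-1]) * np.abs(np.diff(l2)) / np.abs(np.diff(l1))
        work_motor = float(np.sum(fm * np.abs(np.diff(l1))))
        ds = l2[-1] - l2[0]
        energy_spring = f0 * ds + 0.5 * k * ds**2
        assert work_motor == pytest.approx(energy_spring, rel=0.01)


@pytest.fixture(scope="module")
def sweep(mech_config, act_config):
    return sweep_endpoints(mech_config, act_config, n_samples=51)


class TestSweep:
    def test_81_unique_rows(self, sweep):
        table, _ = sweep
        assert len(table) == 81
        assert table.index.is_unique

    def test_spring_force_consistent_with_law(self, sweep, act_config):
        table, _ = sweep
        expected = (act_config.spring_preload_n
                    + act_config.spring_stiffness_n_mm * table["max_spring_stretch_mm"])
        assert np.allclose(table["max_spring_force_N"], expected, atol=1e-9)

    def test_distal_biceps_ulna_end_increases_motor_stretch(self, sweep):
        table, _ = sweep
        for j, k, l in itertools.product(range(1, 4), repeat=3):
            v = [table.loc[f"BU{i}-BH{j}-TU{k}-TH{l}", "max_motor_stretch_mm"]
                 for i in (1, 2, 3)]
            assert v[0] < v[1] < v[2]

    def test_selection_is_feasible_and_minimal(self, sweep):
        table, selected = sweep
        feas = table[table["feasible"]]
        assert len(feas) > 0
        assert selected in feas.index
        assert feas.loc[selected, "max_motor_force_N"] == feas["max_motor_force_N"].min()
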