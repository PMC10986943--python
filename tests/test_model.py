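import numpy as np
import pytest

from wingkin.geometry import RigidTransform
from wingkin.model import (MODEL_PRESETS, ConstrainedFitOptions,
                           SkeletonPoseModel, fit_skeleton_constrained)
from wingkin.registration import FitOptions


def options(seed=3, downsample=300):
    return ConstrainedFitOptions(pose_options=FitOptions(seed=seed, downsample=downsample,
                                                         n_starts=4))


@pytest.fixture(scope="module")
def noiseless_model(noiseless_dataset):
    return SkeletonPoseModel.from_dataset(noiseless_dataset)


@pytest.fixture(scope="module")
def onedof_fit(noiseless_model):
    return noiseless_model.fit("onedof", options())


class TestUnconstrainedBaseline:
    def test_noiseless_baseline_is_essentially_exact(self, noiseless_model):
        res = noiseless_model.fit("unrestrained", options())
        assert res.mean_residual_mm < 1e-6
        assert res.joints is None
        assert not res.is_constrained

    def test_transform_recovery_against_ground_truth(self, noiseless_model,
                                                     noiseless_dataset):
        res = noiseless_model.fit("unrestrained", options())
        for posture in noiseless_dataset.non_reference_postures:
            for bone in ("humerus", "ulna", "radius", "metacarpal"):
                est = res.transform(posture, bone)
                true = noiseless_dataset.transforms[posture][bone]
                assert (est.inverse() @ true).rotation_angle_deg() < 0.5
                assert np.linalg.norm(est.translation - true.translation) < 0.1


class TestConstrainedFit:
    def test_true_types_reach_tiny_residual_and_feasibility(self, onedof_fit, smoke=None):
        assert onedof_fit.mean_residual_mm < 1e-2
        assert onedof_fit.max_coincidence_mm <= 1e-4
        assert onedof_fit.max_axis_dot <= 1e-6
        assert onedof_fit.status == "converged"

    def test_joint_center_recovery(self, onedof_fit, noiseless_dataset):
        truth = noiseless_dataset.truth
        for jid, est in onedof_fit.joints.items():
            true = truth.joints[jid]
            d = est.center - true.center
            if true.joint_type == "revolute":
                # hinge centers are identifiable only transverse to the axis
                d = d - (d @ true.u_b3) * true.u_b3
            assert np.linalg.norm(d) < 0.5, f"joint {jid}"

    def test_revolute_axis_recovery(self, onedof_fit, noiseless_dataset):
        truth = noiseless_dataset.truth
        for jid in (1, 2):
            est, true = onedof_fit.joints[jid], truth.joints[jid]
            ang = np.degrees(np.arccos(min(1.0, abs(est.u_b3 @ true.u_b3))))
            assert ang < 2.0

    def test_universal_pair_is_consistent_with_true_motion(self, onedof_fit,
                                                           noiseless_dataset):
        # with two observed postures the universal pair is identifiable only
        # up to a one-parameter family; the estimate must lie in that family,
        # i.e. satisfy the ground-truth relative rotations exactly
        est = onedof_fit.joints[3]
        for posture in noiseless_dataset.non_reference_postures:
            tf = noiseless_dataset.transforms[posture]
            rel = tf["radius"].matrix.T @ tf["metacarpal"].matrix
            assert abs(est.u_a1 @ rel @ est.u_b3) < 1e-6

    def test_fitted_joint_angles_match_commanded_stroke(self, onedof_fit,
                                                        noiseless_dataset):
        ang = onedof_fit.joint_angles_deg()
        for jid, col, expected in ((1, "half_extension", 15.54),
                                   (1, "flexion", 37.18),
                                   (2, "half_extension", 22.84),
                                   (2, "flexion", 55.65)):
            assert abs(ang.loc[jid, col]) == pytest.approx(expected, abs=0.1)

    def test_misspecified_types_fit_strictly_worse(self, noiseless_model, onedof_fit):
        res_rev = noiseless_model.fit("revolute", options())
        assert res_rev.mean_residual_mm > 10 * max(onedof_fit.mean_residual_mm, 1e-3)
        assert res_rev.max_coincidence_mm <= 1e-4  # still feasible, just worse

    def test_functional_wrapper(self, noiseless_dataset):
        res = fit_skeleton_constrained(
            noiseless_dataset.reference,
            {p: noiseless_dataset.clouds[p]
             for p in noiseless_dataset.non_reference_postures},
            joint_types="ball", options=options())
        assert res.max_coincidence_mm <= 1e-4


@pytest.fixture(scope="module")
def comparison(noisy_dataset):
    model = SkeletonPoseModel.from_dataset(noisy_dataset)
    return model.compare(("unrestrained", "ball", "universal", "revolute"),
                         options=options(seed=7))


class TestComparison:
    def test_baseline_relative_deviation_is_zero(self, comparison):
        assert comparison.table.loc["unrestrained", "relative_deviation_pct"] == 0.0

    def test_mean_residual_nests_with_constraint_strictness(self, comparison):
        t = comparison.table["mean_mm"]
        assert t["unrestrained"] <= t["ball"] + 1e-12
        assert t["ball"] <= t["universal"] + 1e-12
        assert t["universal"] <= t["revolute"] + 1e-12

    def test_constrained_models_feasible(self, comparison):
        for name in ("ball", "universal", "revolute"):
            res = comparison.results[name]
            assert res.max_coincidence_mm <= 1e-4
            assert res.status == "converged"

    def test_summary_mentions_every_model(self, comparison):
        text = comparison.summary()
        for name in ("unrestrained", "ball", "universal", "revolute"):
            assert name in text


class TestInvarianceAndSurface:
    def test_residual_table_invariant_under_global_rigid_motion(self, noiseless_dataset):
        base_model = SkeletonPoseModel.from_dataset(noiseless_dataset)
        base = base_model.fit("onedof", options())
        g = RigidTransform([14.0, -8.0, 23.0], [5.0, -12.0, 30.0])
        moved = {p: {b: c.transformed(g) for b, c in
                     noiseless_dataset.clouds[p].items()}
                 for p in noiseless_dataset.non_reference_postures}
        moved_model = SkeletonPoseModel(noiseless_dataset.reference, moved)
        res = moved_model.fit("onedof", options())
        assert np.allclose(res.residual_table.to_numpy(),
                           base.residual_table.to_numpy(), atol=1e-6)

    def test_summary_and_dict_round_trip(self, onedof_fit):
        text = onedof_fit.summary()
        assert "Mean residual" in text and "revolute" in text
        d = onedof_fit.as_dict()
        assert set(d["transforms"]) == {"half_extension", "flexion"}

    def test_table1_view_has_three_bones(self, onedof_fit):
        assert list(onedof_fit.table1_view().columns) == ["ulna", "humerus", "metacarpal"]

    def test_missing_posture_bone_rejected(self, noiseless_dataset):
        broken = {p: dict(noiseless_dataset.clouds[p])
                  for p in noiseless_dataset.non_reference_postures}
        del broken["flexion"]["radius"]
        with pytest.raises(ValueError, match="radius"):
            SkeletonPoseModel(noiseless_dataset.reference, broken)

    def test_unknown_preset_rejected(self, noiseless_model):
        with pytest.raises(ValueError, match="preset"):
            noiseless_model.fit("bogus")
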