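import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from heptahelix.activation import (fingerprint, helix_movements,
                                   helix_rotation, ionic_lock_status,
                                   superpose_by_bw)
from heptahelix.errors import InsufficientDataError
from heptahelix.synthetic import (ContactPair, MovementPlan, RigidMotion,
                                  SyntheticBundleSpec, build_bundle,
                                  make_state_pair, DEFAULT_ACTIVATION_PLAN)

from conftest import translate_residues

SEPARATING_PLAN = MovementPlan(
    end_moves={6: {"extracellular": {"radial": 8.0},
                   "intracellular": {"radial": 12.0}}},
    toggle_target_A=4.6)


class TestIonicLock:
    def test_planted_bridge_present(self, lock_bundle):
        model, _ann, bwmap = lock_bundle
        status = ionic_lock_status(model, bwmap)
        assert status["present"] is True
        assert status["distance_A"] == pytest.approx(3.0, abs=0.3)

    def test_separated_pair_absent(self, lock_bundle):
        model, _ann, bwmap = lock_bundle
        far = translate_residues(model, "A", 601, 631, (10.0, 4.0, 0.0))
        status = ionic_lock_status(far, bwmap)
        assert status["present"] is False
        assert status["distance_A"] > 4.0

    def test_wrong_residue_types_not_applicable(self):
        model, _ann, bwmap = build_bundle(SyntheticBundleSpec(seed=0))
        status = ionic_lock_status(model, bwmap)  # polyalanine bundle
        assert status["regime"] == "not_applicable"
        assert status["present"] is None


class TestFingerprint:
    def test_inactive_then_active_then_indeterminate(self):
        spec = SyntheticBundleSpec(seed=2)
        inactive, active, _ann, bwmap = make_state_pair(spec, SEPARATING_PLAN)
        fp_in = fingerprint(inactive, bwmap)
        assert fp_in.state_call == "inactive_like"
        assert fp_in.tyrosine_toggle["regime"] == "apart"
        fp_ac = fingerprint(active, bwmap)
        assert fp_ac.state_call == "active_like"
        assert fp_ac.ionic_lock["distance_A"] > 10.0
        assert fp_ac.tyrosine_toggle["distance_A"] == pytest.approx(4.6, abs=0.3)
        assert fp_ac.tyrosine_toggle["regime"] == "water_mediated_possible"
        # lock broken but toggle still apart -> no call either way
        lockless = MovementPlan(end_moves=SEPARATING_PLAN.end_moves)
        _, ambiguous, _, _ = make_state_pair(spec, lockless)
        assert fingerprint(ambiguous, bwmap).state_call == "indeterminate"

    def test_invariant_under_rigid_motion(self):
        spec = SyntheticBundleSpec(seed=6)
        inactive, _active, _ann, bwmap = make_state_pair(spec)
        rot = Rotation.from_euler("xyz", [120, -40, 66], degrees=True).as_matrix()
        moved = inactive.transformed(rot, np.array([20.0, -7.0, 3.0]))
        fp_a, fp_b = fingerprint(inactive, bwmap), fingerprint(moved, bwmap)
        assert fp_a.state_call == fp_b.state_call
        assert fp_a.ionic_lock["distance_A"] == pytest.approx(
            fp_b.ionic_lock["distance_A"], abs=1e-6)
        assert fp_a.core_contacts == fp_b.core_contacts


class TestSuperposition:
    def test_self_superposition_identity(self, lock_bundle):
        model, _ann, bwmap = lock_bundle
        sup = superpose_by_bw(model, model, bwmap, bwmap)
        assert sup.rmsd_A == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-9)

    def test_recovers_planted_transform(self, lock_bundle):
        model, _ann, bwmap = lock_bundle
        rot = Rotation.from_euler("zyx", [25, 50, -75], degrees=True).as_matrix()
        trans = np.array([1.0, -2.0, 3.0])
        moved = model.transformed(rot, trans)
        sup = superpose_by_bw(model, moved, bwmap, bwmap)
        assert sup.rmsd_A < 1e-6
        np.testing.assert_allclose(sup.rotation, rot.T, atol=1e-8)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
        # symmetry of the residual
        back = superpose_by_bw(moved, model, bwmap, bwmap)
        assert back.rmsd_A == pytest.approx(sup.rmsd_A, abs=1e-9)

    def test_displaced_helix_rmsd_matches_numerical_minimum(self):
        model, _ann, bwmap = build_bundle(
            SyntheticBundleSpec(seed=12, n_helices=3))
        moved = translate_residues(model, "A", 201, 231, (3.0, 1.0, -2.0))
        sup = superpose_by_bw(model, moved, bwmap, bwmap)

        ref = np.stack([r.atom("CA").coord for r in model.chain("A")])
        mob = np.stack([r.atom("CA").coord for r in moved.chain("A")])

        def rmsd_of(params):
            rot = Rotation.from_rotvec(params[:3]).as_matrix()
            out = mob @ rot.T + params[3:]
            return np.sqrt(np.mean(np.sum((out - ref) ** 2, axis=-1)))

        best = min(minimize(rmsd_of, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12,
                                     "maxiter": 20000}).fun
                   for x0 in (np.zeros(6), np.array([.1, -.1, .2, 1., 0., -1.])))
        assert sup.rmsd_A == pytest.approx(best, abs=1e-3)

    def test_too_few_pairs(self, lock_bundle):
        model, _ann, bwmap = lock_bundle
        with pytest.raises(InsufficientDataError):
            superpose_by_bw(model, model, bwmap, bwmap, core_selection=())


class TestHelixMovements:
    def test_identical_pair_all_zero(self):
        inactive, active, ann, bwmap = make_state_pair(
            SyntheticBundleSpec(seed=4), MovementPlan())
        rep = helix_movements(inactive, active, bwmap, bwmap, ann)
        for helix, ends in rep.per_helix.items():
            for entry in ends.values():
                assert abs(entry["radial"]) < 1e-6
                assert abs(entry["axial"]) < 1e-6
        assert rep.tm6_rotation_deg == pytest.approx(0.0, abs=1e-6)

    def test_rigidly_moved_copy_all_zero(self, lock_bundle):
        model, ann, bwmap = lock_bundle
        rot = Rotation.from_euler("xyz", [15, 25, 35], degrees=True).as_matrix()
        moved = model.transformed(rot, np.array([8.0, 1.0, -4.0]))
        rep = helix_movements(model, moved, bwmap, bwmap, ann)
        for ends in rep.per_helix.values():
            for entry in ends.values():
                assert np.linalg.norm(entry["displacement"]) < 1e-6

    def test_swung_ic_half_recovered(self):
        import math
        base = SyntheticBundleSpec(seed=13)
        model0, ann, bwmap = build_bundle(base)
        angle = 2 * math.pi * 5 / 7  # TM6 azimuth in the builder frame
        outward = (5 * math.cos(angle), 5 * math.sin(angle), 0.0)
        model1, _, _ = build_bundle(base.with_features(
            RigidMotion(6, translation=outward, segment="ic_half")))
        rep = helix_movements(model0, model1, bwmap, bwmap, ann)
        entry = rep.per_helix["TM6"]["intracellular"]
        assert entry["radial"] == pytest.approx(5.0, abs=0.5)
        assert abs(rep.per_helix["TM6"]["extracellular"]["radial"]) < 0.5

    def test_activation_plan_signs_and_rotation(self):
        inactive, active, ann, bwmap = make_state_pair(
            SyntheticBundleSpec(seed=1), DEFAULT_ACTIVATION_PLAN)
        rep = helix_movements(inactive, active, bwmap, bwmap, ann)
        assert rep.per_helix["TM6"]["intracellular"]["radial"] > 1.0   # out
        assert rep.per_helix["TM5"]["intracellular"]["radial"] < -1.0  # in
        assert rep.per_helix["TM7"]["intracellular"]["radial"] < -1.0  # in
        assert rep.per_helix["TM1"]["intracellular"]["radial"] > 1.0   # out
        assert rep.per_helix["TM3"]["intracellular"]["axial"] < 0      # down
        assert rep.tm6_rotation_deg == pytest.approx(30.0, abs=2.0)
        payload = rep.to_dict()
        assert payload["helices"]["TM6"]["intracellular"]["radial_A"] > 1.0


class TestHelixRotation:
    def test_identity_zero_and_antisymmetry(self):
        plan = MovementPlan(tm6_rotation_deg=30.0)
        inactive, active, ann, bwmap = make_state_pair(
            SyntheticBundleSpec(seed=3), plan)
        fwd = helix_rotation(inactive, active, bwmap, bwmap, ann)
        rev = helix_rotation(active, inactive, bwmap, bwmap, ann)
        assert fwd == pytest.approx(30.0, abs=2.0)
        assert rev == pytest.approx(-fwd, abs=1e-6)
        zero = helix_rotation(inactive, inactive, bwmap, bwmap, ann)
        assert zero == pytest.approx(0.0, abs=1e-9)
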