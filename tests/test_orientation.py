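import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from xltrap.orientation import (
    NoseDefinition,
    any_contact_persistence,
    contact_persistence,
    distance_trace,
    ensemble_orientation,
    euler_angles,
    frame_for_body,
    principal_frame,
    relative_rotation,
    rotation_from_angles,
)
from xltrap.structures import (
    ResidueRef,
    StructureError,
    TrajectoryEnsemble,
    combine_structures,
)
from xltrap.synthetic import simulate_trajectory


def ellipsoid_points(scales=(3.0, 2.0, 1.0)) -> np.ndarray:
    """Deterministic point set whose sample covariance is exactly
    diagonal, so the principal axes are the scaled coordinate axes."""
    pts = []
    for k in (1.0, 0.5):
        for axis in range(3):
            for sign in (1.0, -1.0):
                p = np.zeros(3)
                p[axis] = sign * k * scales[axis]
                pts.append(p)
    return np.array(pts)


class TestPrincipalFrame:
    def test_axis_aligned_ellipsoid(self):
        pts = ellipsoid_points()
        frame = principal_frame(pts, nose_point=[100.0, 0, 0], reference_direction=[0, 1, 0])
        np.testing.assert_allclose(frame.longitudinal, [1, 0, 0], atol=1e-9)
        np.testing.assert_allclose(frame.vertical, [0, 1, 0], atol=1e-9)
        # aircraft handedness: north x east = down
        np.testing.assert_allclose(
            np.cross(frame.longitudinal, frame.transverse), frame.vertical, atol=1e-12
        )

    def test_equivariant_under_rotation(self):
        pts = ellipsoid_points()
        R = Rotation.random(random_state=4).as_matrix()
        nose = np.array([100.0, 0, 0])
        ref = np.array([0.0, 1, 0])
        f0 = principal_frame(pts, nose, ref)
        f1 = principal_frame(pts @ R.T, R @ nose, R @ ref)
        np.testing.assert_allclose(f1.matrix, R @ f0.matrix, atol=1e-8)

    def test_nose_flip_preserves_handedness(self):
        pts = ellipsoid_points()
        f_pos = principal_frame(pts, [100.0, 0, 0], [0, 1, 0])
        f_neg = principal_frame(pts, [-100.0, 0, 0], [0, 1, 0])
        np.testing.assert_allclose(f_neg.longitudinal, -f_pos.longitudinal, atol=1e-12)
        np.testing.assert_allclose(f_neg.transverse, -f_pos.transverse, atol=1e-12)
        np.testing.assert_allclose(
            np.cross(f_neg.longitudinal, f_neg.transverse), f_neg.vertical, atol=1e-12
        )

    def test_collinear_points_raise(self):
        line = np.outer(np.linspace(0, 10, 20), [1.0, 0, 0])
        with pytest.raises(StructureError):
            principal_frame(line, [100.0, 0, 0])

    def test_near_tied_eigenvalues_warn(self):
        pts = ellipsoid_points(scales=(2.0, 1.0, 0.999))
        with pytest.warns(RuntimeWarning, match="tied"):
            principal_frame(pts, [100.0, 0, 0], [0, 1, 0])


class TestRelativeRotationAndEuler:
    def make_frame(self, R=np.eye(3)):
        pts = ellipsoid_points() @ R.T
        return principal_frame(pts, R @ np.array([100.0, 0, 0]), R @ np.array([0.0, 1, 0]))

    def test_identical_frames_give_identity(self):
        f = self.make_frame()
        np.testing.assert_allclose(relative_rotation(f, f), np.eye(3), atol=1e-10)

    def test_planted_yaw_rotation_recovered(self):
        f_rec = self.make_frame()
        # yaw the arrestin by 30 degrees about the shared vertical axis
        # (here the lab +y, since PC2 of the test ellipsoid is y)
        G = Rotation.from_euler("y", 30, degrees=True).as_matrix()
        f_arr = self.make_frame(G)
        ang = euler_angles(relative_rotation(f_rec, f_arr))
        assert ang.as_tuple() == pytest.approx((0.0, 0.0, 30.0), abs=1e-6)

    def test_swapping_bodies_transposes(self):
        f_a = self.make_frame()
        f_b = self.make_frame(Rotation.random(random_state=8).as_matrix())
        np.testing.assert_allclose(
            relative_rotation(f_a, f_b), relative_rotation(f_b, f_a).T, atol=1e-10
        )

    def test_identity_rotation_gives_zero_angles(self):
        assert euler_angles(np.eye(3)).as_tuple() == pytest.approx((0.0, 0.0, 0.0))

    def test_pure_yaw(self):
        ang = euler_angles(rotation_from_angles(0, 0, 25))
        assert ang.as_tuple() == pytest.approx((0.0, 0.0, 25.0), abs=1e-9)

    def test_round_trip_fixed_triple(self):
        ang = euler_angles(rotation_from_angles(13, -17, 25))
        assert ang.as_tuple() == pytest.approx((13.0, -17.0, 25.0), abs=1e-9)

    @given(
        pitch=st.floats(-89.0, 89.0),
        roll=st.floats(-179.0, 179.0),
        yaw=st.floats(-179.0, 179.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_property(self, pitch, roll, yaw):
        ang = euler_angles(rotation_from_angles(pitch, roll, yaw))
        assert ang.as_tuple() == pytest.approx((pitch, roll, yaw), abs=1e-8)

    def test_gimbal_lock_flagged_and_folded(self):
        ang = euler_angles(rotation_from_angles(90, 10, 20))
        assert ang.gimbal_locked
        assert ang.roll == 0.0
        # the residual in-plane rotation is preserved in yaw
        assert ang.yaw == pytest.approx(10.0, abs=1e-6)

    def test_non_rotation_rejected(self):
        with pytest.raises(ValueError):
            euler_angles(np.diag([1.0, 1.0, -1.0]))


@pytest.fixture(scope="module")
def oriented_trajectory(coil_pair):
    rec, mob = coil_pair
    cx = combine_structures(rec, mob)
    nose_r = NoseDefinition((ResidueRef("R", rec.residues[-1].number),))
    nose_a = NoseDefinition((ResidueRef("A", mob.residues[-1].number),))
    # stabilize the vertical sign with each body's own base PC2
    nose_r = NoseDefinition(nose_r.residues, tuple(frame_for_body(cx, "R", nose_r).vertical))
    nose_a = NoseDefinition(nose_a.residues, tuple(frame_for_body(cx, "A", nose_a).vertical))
    traj, planted = simulate_trajectory(
        rec, mob, nose_r, nose_a, angle_sds_deg=(5, 5, 10),
        translation_sd=0.5, n_frames=60, seed=11,
    )
    rng_pairs = np.random.default_rng(3)
    pairs = [
        (
            ResidueRef("R", int(rng_pairs.integers(1, len(rec.residues) + 1))),
            ResidueRef("A", int(rng_pairs.integers(1, len(mob.residues) + 1))),
        )
        for _ in range(12)
    ]
    return rec, mob, pairs, nose_r, nose_a, traj, planted


class TestEnsembleOrientation:
    def test_static_ensemble_constant_angles_zero_rmsd(self, oriented_trajectory):
        rec, mob, _, nose_r, nose_a, traj, _ = oriented_trajectory
        static = TrajectoryEnsemble(traj.topology, np.repeat(traj.frames[:1], 4, axis=0))
        table = ensemble_orientation(static, "R", "A", nose_r, nose_a)
        assert table["pitch_deg"].nunique() == 1
        np.testing.assert_allclose(table["rmsd_A"], 0.0, atol=1e-9)

    def test_planted_angles_recovered(self, oriented_trajectory):
        *_, nose_r, nose_a, traj, planted = oriented_trajectory
        got = ensemble_orientation(traj, "R", "A", nose_r, nose_a)
        for col in ("pitch_deg", "roll_deg", "yaw_deg"):
            np.testing.assert_allclose(got[col], planted[col], atol=0.5)

    def test_reversed_frames_reverse_trace(self, oriented_trajectory):
        *_, nose_r, nose_a, traj, _ = oriented_trajectory
        rev = TrajectoryEnsemble(traj.topology, traj.frames[::-1].copy())
        fwd_table = ensemble_orientation(traj, "R", "A", nose_r, nose_a)
        rev_table = ensemble_orientation(rev, "R", "A", nose_r, nose_a)
        np.testing.assert_allclose(
            rev_table["yaw_deg"].to_numpy(), fwd_table["yaw_deg"].to_numpy()[::-1], atol=1e-9
        )

    def test_invariant_under_global_rigid_transform(self, oriented_trajectory):
        *_, nose_r, nose_a, traj, _ = oriented_trajectory
        R = Rotation.random(random_state=21).as_matrix()
        t = np.array([30.0, -12.0, 7.0])
        moved = TrajectoryEnsemble(traj.topology, traj.frames @ R.T + t)
        # nose reference directions are body-attached, so rotate them too
        nr = NoseDefinition(nose_r.residues, tuple(R @ np.array(nose_r.reference_direction)))
        na = NoseDefinition(nose_a.residues, tuple(R @ np.array(nose_a.reference_direction)))
        base = ensemble_orientation(traj, "R", "A", nose_r, nose_a)
        mov = ensemble_orientation(moved, "R", "A", nr, na)
        for col in ("pitch_deg", "roll_deg", "yaw_deg", "rmsd_A"):
            np.testing.assert_allclose(mov[col], base[col], atol=1e-6)


class TestDistanceTrace:
    def test_single_frame_degenerate_stats(self, oriented_trajectory):
        rec, mob, pairs, _, _, traj, _ = oriented_trajectory
        single = TrajectoryEnsemble(traj.topology, traj.frames[:1])
        stats = distance_trace(single, pairs)
        np.testing.assert_allclose(stats["min_A"], stats["max_A"])
        np.testing.assert_allclose(stats["min_A"], stats["median_A"])

    def test_sinusoidal_distance_fractions_match_analytics(self):
        # two single-atom "residues" oscillating between 8 and 18 Å
        from xltrap.structures import Residue, Structure

        res_a = Residue("R", 1, "", "ALA"); res_a.atoms = {"CA": 0, "CB": 1}
        res_b = Residue("A", 1, "", "ALA"); res_b.atoms = {"CA": 2, "CB": 3}
        topo = Structure(
            [res_a, res_b], ["CA", "CB", "CA", "CB"], ["C"] * 4, np.zeros((4, 3))
        )
        n = 20000
        phases = 2 * np.pi * np.arange(n) / n
        d = 13.0 + 5.0 * np.sin(phases)
        frames = np.zeros((n, 4, 3))
        frames[:, 3, 0] = d
        traj = TrajectoryEnsemble(topo, frames)
        stats = distance_trace(traj, [(ResidueRef("R", 1), ResidueRef("A", 1))])
        row = stats.iloc[0]
        assert row["ever_within_10.2A"]
        # fraction of a sinusoid below 15: arcsin argument (15-13)/5
        expected = 0.5 + np.arcsin(2.0 / 5.0) / np.pi
        assert row["fraction_within_15A"] == pytest.approx(expected, abs=0.01)

    def test_quartiles_match_bruteforce_sort(self, oriented_trajectory):
        rec, mob, pairs, _, _, traj, _ = oriented_trajectory
        stats = distance_trace(traj, pairs)
        from xltrap.structures import anchor_coordinate

        for i, (a, b) in enumerate(pairs[:4]):
            ds = []
            for k in range(traj.n_frames):
                fs = traj.frame_structure(k)
                ds.append(
                    np.linalg.norm(anchor_coordinate(fs, a) - anchor_coordinate(fs, b))
                )
            q25, med, q75 = np.percentile(ds, [25, 50, 75])
            assert stats["q25_A"][i] == pytest.approx(q25, abs=1e-9)
            assert stats["median_A"][i] == pytest.approx(med, abs=1e-9)
            assert stats["q75_A"][i] == pytest.approx(q75, abs=1e-9)

    def test_unresolvable_pair_named(self, oriented_trajectory):
        *_, traj, _ = oriented_trajectory
        with pytest.raises(StructureError, match="R:999"):
            distance_trace(traj, [(ResidueRef("R", 999), ResidueRef("A", 1))])


class TestContactPersistence:
    @pytest.fixture()
    def four_frame_traj(self):
        from xltrap.structures import Residue, Structure

        res_a = Residue("R", 1, "", "ALA"); res_a.atoms = {"CA": 0}
        res_b = Residue("A", 1, "", "ALA"); res_b.atoms = {"CA": 1}
        res_c = Residue("A", 2, "", "ALA"); res_c.atoms = {"CA": 2}
        topo = Structure([res_a, res_b, res_c], ["CA"] * 3, ["C"] * 3, np.zeros((3, 3)))
        frames = np.zeros((4, 3, 3))
        # residue A:1 close in frames 0-2, far in frame 3
        frames[:, 1, 0] = [3.0, 3.5, 3.9, 12.0]
        # residue A:2 close only in frame 3
        frames[:, 2, 0] = [20.0, 20.0, 20.0, 3.0]
        return TrajectoryEnsemble(topo, frames)

    def test_counting(self, four_frame_traj):
        table = contact_persistence(
            four_frame_traj, [(ResidueRef("R", 1), ResidueRef("A", 1))]
        )
        assert table["persistence_fraction"][0] == pytest.approx(0.75)

    def test_zero_cutoff_never_in_contact(self, four_frame_traj):
        table = contact_persistence(
            four_frame_traj, [(ResidueRef("R", 1), ResidueRef("A", 1))], cutoff=0.0
        )
        assert table["persistence_fraction"][0] == 0.0

    def test_group_persistence_bounds_single_pairs(self, four_frame_traj):
        pairs = [
            (ResidueRef("R", 1), ResidueRef("A", 1)),
            (ResidueRef("R", 1), ResidueRef("A", 2)),
        ]
        singles = contact_persistence(four_frame_traj, pairs)["persistence_fraction"]
        grouped = any_contact_persistence(four_frame_traj, pairs)
        assert grouped >= singles.max()
        assert grouped == pytest.approx(1.0)
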