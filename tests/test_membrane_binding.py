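"""Geometry and classification of membrane binding and orientation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vspkit import membrane_binding as mb
from vspkit.errors import (
    ConfigurationError,
    DegenerateOrientationError,
    MissingAnnotationError,
)
from vspkit.synthetic import TrajectorySchedule, gen_membrane_trajectory


def make_frame(coords: dict, phosphorus_prox=("P0",), anchors=None, pd=("PD0",), c2=("C20",),
               masses=None, resolution="AT", bilayer="POPC"):
    """Minimal hand-built frame for unit tests."""
    anchors = anchors or {r: r for r in mb.ANCHOR_ROLES}
    for r in mb.ANCHOR_ROLES:
        coords.setdefault(anchors[r], (0.0, 0.0, 0.0))
    atom_ids = list(coords)
    meta = mb.SystemMeta(
        resolution=resolution,
        bilayer=bilayer,
        anchors=anchors,
        selections={"pd": tuple(pd), "c2": tuple(c2)},
        phosphorus={"proximal": tuple(phosphorus_prox)},
        masses=masses,
    )
    arr = np.array([coords[a] for a in atom_ids], dtype=float)
    return mb.Frame(0.0, arr, {a: i for i, a in enumerate(atom_ids)}, meta)


class TestPhosphorusPlane:
    def test_constant_plane(self):
        f = make_frame({"P0": (0, 0, 5.0), "PD0": (0, 0, 1), "C20": (1, 0, 1)})
        assert mb.phosphorus_plane_z(f) == 5.0

    def test_arithmetic_mean(self):
        f = make_frame({"P0": (0, 0, 4.8), "P1": (1, 0, 5.2), "PD0": (0, 0, 1), "C20": (1, 0, 1)},
                       phosphorus_prox=("P0", "P1"))
        assert mb.phosphorus_plane_z(f) == pytest.approx(5.0)

    def test_jittered_atoms_match_summation_oracle(self):
        rng = np.random.default_rng(0)
        z = 5.0 + rng.normal(scale=0.1, size=100)
        coords = {f"P{i}": (0.0, 0.0, zi) for i, zi in enumerate(z)}
        coords.update({"PD0": (0, 0, 1), "C20": (1, 0, 1)})
        f = make_frame(coords, phosphorus_prox=tuple(f"P{i}" for i in range(100)))
        oracle = sum(z) / len(z)  # independent plain summation
        assert mb.phosphorus_plane_z(f) == pytest.approx(oracle, abs=1e-12)

    def test_missing_monolayer_errors(self):
        f = make_frame({"P0": (0, 0, 5.0), "PD0": (0, 0, 1), "C20": (1, 0, 1)})
        with pytest.raises(MissingAnnotationError):
            mb.phosphorus_plane_z(f, "distal")


class TestRelTopZ:
    def test_unit_conversion_and_sign(self):
        f = make_frame({"P0": (0, 0, 5.0), "PD0": (0, 0, 4.7), "C20": (1, 0, 1)})
        assert mb.rel_top_z(f, ("PD0",)) == pytest.approx(-3.0)

    def test_maximum_over_selection(self):
        f = make_frame(
            {"P0": (0, 0, 5.0), "a": (0, 0, 4.5), "b": (0, 0, 4.8), "c": (0, 0, 4.2),
             "PD0": (0, 0, 1), "C20": (1, 0, 1)}
        )
        assert mb.rel_top_z(f, ("a", "b", "c")) == pytest.approx(-2.0)

    def test_random_atoms_match_bruteforce_max(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(2, 6, size=50)
        coords = {f"a{i}": (0.0, 0.0, zi) for i, zi in enumerate(z)}
        coords.update({"P0": (0, 0, 5.0), "PD0": (0, 0, 1), "C20": (1, 0, 1)})
        f = make_frame(coords)
        sel = tuple(f"a{i}" for i in range(50))
        oracle = (max(z) - 5.0) * 10
        assert mb.rel_top_z(f, sel) == pytest.approx(oracle)

    def test_empty_selection_errors(self):
        f = make_frame({"P0": (0, 0, 5.0), "PD0": (0, 0, 1), "C20": (1, 0, 1)})
        with pytest.raises(MissingAnnotationError):
            mb.rel_top_z(f, ())


class TestBindingState:
    @pytest.mark.parametrize(
        "rel, res, bil, expected",
        [
            (-3.0, "AT", "POPC", False),      # cutoff 0 Å
            (-3.0, "AT", "POPC_PIP3", True),  # cutoff −4 Å
            (-12.0, "CG", "POPC_PIP3", True), # boundary equality is bound
            (-2.0, "CG", "POPC", True),
            (-2.01, "CG", "POPC", False),
            (0.0, "AT", "POPC", True),
        ],
    )
    def test_cutoff_table(self, rel, res, bil, expected):
        assert mb.binding_state(rel, res, bil) is expected

    def test_unknown_system_errors(self):
        with pytest.raises(ConfigurationError):
            mb.binding_state(0.0, "CG", "DOPC")

    @given(z0=st.floats(-20, 20), dz=st.floats(0, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_depth(self, z0, dz):
        """If bound at z0, bound at any higher z."""
        if mb.binding_state(z0, "CG", "POPC_PIP3"):
            assert mb.binding_state(z0 + dz, "CG", "POPC_PIP3")


class TestOrientation:
    def test_midpoint_arithmetic(self):
        coords = {
            "arg281_ca": (0, 0, 0),
            "lys516_ca": (2, 0, 0),
            "arg520_ca": (0, 2, 0),
            "lys555_ca": (0, 0, 2),
            "lys558_ca": (0, 0, 2),
            "P0": (0, 0, 5.0), "PD0": (0, 0, 1), "C20": (1, 0, 1),
        }
        f = make_frame(coords)
        v1, v2 = mb.orientation_vectors(f)
        assert np.allclose(v1, (1, 1, 0))
        assert np.allclose(v2, (0, 0, 2))

    def test_random_anchors_match_midpoint_oracle(self):
        rng = np.random.default_rng(3)
        pts = {r: rng.normal(size=3) for r in mb.ORIENTATION_ANCHORS}
        coords = {r: tuple(p) for r, p in pts.items()}
        coords.update({"P0": (0, 0, 5.0), "PD0": (0, 0, 1), "C20": (1, 0, 1)})
        f = make_frame(coords)
        v1, v2 = mb.orientation_vectors(f)
        m1 = [(pts["lys516_ca"][i] + pts["arg520_ca"][i]) / 2 - pts["arg281_ca"][i] for i in range(3)]
        m2 = [(pts["lys555_ca"][i] + pts["lys558_ca"][i]) / 2 - pts["arg281_ca"][i] for i in range(3)]
        assert np.allclose(v1, m1) and np.allclose(v2, m2)

    def test_coincident_anchors_are_degenerate(self):
        f = make_frame({"P0": (0, 0, 5.0), "PD0": (0, 0, 1), "C20": (1, 0, 1)})
        v1, v2 = mb.orientation_vectors(f)  # all anchors at origin
        with pytest.raises(DegenerateOrientationError):
            mb.productive_angle(v1, v2)

    @pytest.mark.parametrize(
        "v1, v2, expected",
        [((1, 0, 0), (0, 1, 0), 0.0), ((1, 0, 0), (0, 0, 1), 90.0), ((0, 1, 0), (1, 0, 0), 180.0)],
    )
    def test_axis_aligned_angles(self, v1, v2, expected):
        assert mb.productive_angle(np.array(v1), np.array(v2)) == pytest.approx(expected)

    def test_cross_order_reflection(self):
        v1, v2 = np.array([1.0, 0, 0]), np.array([0, 1.0, 0.3])
        a = mb.productive_angle(v1, v2, "v1xv2")
        b = mb.productive_angle(v1, v2, "v2xv1")
        assert a + b == pytest.approx(180.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_angle_matches_acos_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v1, v2 = rng.normal(size=3), rng.normal(size=3)
        c = np.cross(v1, v2)
        if np.linalg.norm(c) < 1e-6:
            return
        oracle = np.degrees(np.arccos(np.dot(c, [0, 0, 1]) / np.linalg.norm(c)))
        assert mb.productive_angle(v1, v2) == pytest.approx(oracle, abs=1e-9)

    @given(st.integers(0, 10_000), st.floats(0, 2 * np.pi))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_invariant_under_z_rotation_and_translation(self, seed, theta):
        rng = np.random.default_rng(seed)
        v1, v2 = rng.normal(size=3), rng.normal(size=3)
        if np.linalg.norm(np.cross(v1, v2)) < 1e-6:
            return
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        base = mb.productive_angle(v1, v2)
        # translation cancels in the vectors themselves; rotation about z
        # preserves the z-component and norm of the cross product
        assert mb.productive_angle(rot @ v1, rot @ v2) == pytest.approx(base, abs=1e-8)

    @pytest.mark.parametrize("angle, expected", [(0.0, True), (30.0, True), (30.1, False), (180.0, False)])
    def test_productive_band_inclusive(self, angle, expected):
        assert mb.classify_productive(angle) is expected


class TestComZ:
    def test_uniform_midpoint(self):
        f = make_frame({"P0": (0, 0, 5.0), "a": (0, 0, 4.8), "b": (0, 0, 4.6),
                        "PD0": (0, 0, 1), "C20": (1, 0, 1)})
        assert mb.com_z(f, ("a", "b")) == pytest.approx(-3.0)

    def test_mass_weighted(self):
        coords = {"P0": (0, 0, 5.0), "a": (0, 0, 4.8), "b": (0, 0, 4.6),
                  "PD0": (0, 0, 1), "C20": (1, 0, 1)}
        masses = {k: 1.0 for k in coords} | {r: 1.0 for r in mb.ANCHOR_ROLES}
        masses["b"] = 3.0
        f = make_frame(dict(coords), masses=masses)
        assert mb.com_z(f, ("a", "b")) == pytest.approx(-3.5)

    def test_random_selection_matches_summation_oracle(self):
        rng = np.random.default_rng(5)
        z = rng.uniform(3, 5, size=20)
        w = rng.uniform(1, 20, size=20)
        coords = {f"a{i}": (0.0, 0.0, zi) for i, zi in enumerate(z)}
        coords.update({"P0": (0, 0, 5.0), "PD0": (0, 0, 1), "C20": (1, 0, 1)})
        masses = {k: 1.0 for k in coords} | {r: 1.0 for r in mb.ANCHOR_ROLES}
        masses.update({f"a{i}": wi for i, wi in enumerate(w)})
        f = make_frame(coords, masses=masses)
        oracle = (sum(wi * zi for wi, zi in zip(w, z)) / sum(w) - 5.0) * 10
        assert mb.com_z(f, tuple(f"a{i}" for i in range(20))) == pytest.approx(oracle)


def test_catalytic_depth_asymmetry():
    coords = {"his332_cb": (0, 0, 4.0), "lys367_ca": (1, 0, 3.975),
              "P0": (0, 0, 5.0), "PD0": (0, 0, 1), "C20": (1, 0, 1)}
    f = make_frame(coords)
    assert mb.catalytic_depth_asymmetry(f) == pytest.approx(0.25)
    assert mb.catalytic_depth_asymmetry(f) < 0.3  # the productive-pose regime


class TestTrajectoryAnalysis:
    def test_oracle_equivalence_on_random_frames(self, random_schedule_trajectory, brute_force_oracle):
        """Full classifier output equals a brute-force recomputation."""
        traj, truth, _ = random_schedule_trajectory
        trace = mb.analyze_trajectory(traj)
        cutoff = truth.params["cutoff_A"]
        for i, frame in enumerate(traj.frames):
            pd_b, c2_b, prod = brute_force_oracle(frame, cutoff)
            rec = trace.records.iloc[i]
            assert rec["pd_bound"] == pd_b
            assert rec["c2_bound"] == c2_b
            assert rec["productive"] == prod

    def test_scheduled_fractions_recovered_exactly(self, scheduled_trajectory):
        traj, truth, schedule = scheduled_trajectory
        summary = mb.summarize_binding(mb.analyze_trajectory(traj))
        assert summary.fraction_pd == pytest.approx(truth.params["fraction_pd_pct"])
        assert summary.fraction_c2 == pytest.approx(truth.params["fraction_c2_pct"])
        assert summary.fraction_productive_both_bound == pytest.approx(
            truth.params["fraction_productive_both_bound_pct"]
        )

    def test_productive_fraction_bounded_by_binding(self, random_schedule_trajectory):
        traj, _, _ = random_schedule_trajectory
        s = mb.summarize_binding(mb.analyze_trajectory(traj))
        assert s.fraction_productive_both_bound <= min(s.fraction_pd, s.fraction_c2) + 1e-9

    def test_lowering_cutoff_never_decreases_fractions(self, scheduled_trajectory):
        traj, _, _ = scheduled_trajectory
        base = mb.summarize_binding(mb.analyze_trajectory(traj))
        lowered = {k: v - 5.0 for k, v in mb.DEFAULT_BINDING_CUTOFFS_A.items()}
        cfg = mb.ClassifierConfig(binding_cutoffs_A=lowered)
        loose = mb.summarize_binding(mb.analyze_trajectory(traj, cfg), cfg)
        assert loose.fraction_pd >= base.fraction_pd
        assert loose.fraction_c2 >= base.fraction_c2

    def test_saturated_trace(self):
        schedule = TrajectorySchedule.from_fractions(50, 1.0, 1.0, 1.0)
        traj, _ = gen_membrane_trajectory(schedule, "AT", "POPC", seed=2)
        s = mb.summarize_binding(mb.analyze_trajectory(traj))
        assert s.fraction_pd == s.fraction_c2 == s.fraction_productive_both_bound == 100.0

    def test_degenerate_frames_warn_and_count_nonproductive(self):
        schedule = TrajectorySchedule.from_fractions(5, 1.0, 1.0, 1.0)
        traj, _ = gen_membrane_trajectory(schedule, "AT", "POPC", seed=2)
        # collapse the orientation anchors of frame 0 onto one point
        f0 = traj.frames[0]
        origin = f0.xyz(traj.meta.anchors["arg281_ca"]).copy()
        for role in mb.ORIENTATION_ANCHORS:
            f0.coords_nm[f0.index[traj.meta.anchors[role]]] = origin
        with pytest.warns(UserWarning, match="collinear"):
            trace = mb.analyze_trajectory(traj)
        assert not trace.records["productive"].iloc[0]
        assert trace.records["degenerate"].iloc[0]

    def test_nonuniform_spacing_uses_time_weights(self):
        schedule = TrajectorySchedule.from_fractions(4, 0.5, 0.5, 0.5)
        traj, _ = gen_membrane_trajectory(schedule, "AT", "POPC", seed=3)
        # stretch the last inter-frame gap: bound frames (the first two) now
        # cover less than half of the simulated time
        for i, t in enumerate([0.0, 1.0, 2.0, 7.0]):
            traj.frames[i].time_ps = t
        s = mb.summarize_binding(mb.analyze_trajectory(traj))
        assert s.fraction_pd < 50.0


@pytest.mark.parametrize(
    "raw, res, expected",
    [(500.0, "CG", 2000.0), (100.0, "AT", 100.0), (0.0, "CG", 0.0)],
)
def test_effective_time(raw, res, expected):
    assert mb.effective_time(raw, res) == expected
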