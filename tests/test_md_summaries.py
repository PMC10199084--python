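import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hittriage.errors import ContractError, FormatError
from hittriage.md_summaries import (
    FrameSeries,
    HBondCriterion,
    StructureFrame,
    Trajectory,
    count_hbonds,
    kabsch_superpose,
    parse_xvg,
    radius_of_gyration,
    read_xyz,
    rmsd_series,
    rmsf_per_atom,
    series_summary,
    write_xvg,
    write_xyz,
)
from hittriage.synthetic_data import TrajectorySpec, generate_trajectory


def quaternion_rmsd(x, y, w=None):
    """Independent minimal-RMSD oracle via the quaternion key matrix."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones(len(x)) if w is None else np.asarray(w, float)
    xc = x - (w[:, None] * x).sum(0) / w.sum()
    yc = y - (w[:, None] * y).sum(0) / w.sum()
    r = (w[:, None] * xc).T @ yc
    k = np.empty((4, 4))
    k[0, 0] = r[0, 0] + r[1, 1] + r[2, 2]
    k[0, 1] = k[1, 0] = r[1, 2] - r[2, 1]
    k[0, 2] = k[2, 0] = r[2, 0] - r[0, 2]
    k[0, 3] = k[3, 0] = r[0, 1] - r[1, 0]
    k[1, 1] = r[0, 0] - r[1, 1] - r[2, 2]
    k[1, 2] = k[2, 1] = r[0, 1] + r[1, 0]
    k[1, 3] = k[3, 1] = r[0, 2] + r[2, 0]
    k[2, 2] = -r[0, 0] + r[1, 1] - r[2, 2]
    k[2, 3] = k[3, 2] = r[1, 2] + r[2, 1]
    k[3, 3] = -r[0, 0] - r[1, 1] + r[2, 2]
    lam = np.linalg.eigvalsh(k)[-1]
    g = (w[:, None] * (xc**2 + yc**2)).sum()
    return math.sqrt(max(0.0, g - 2.0 * lam) / w.sum())


def random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    a, b, c, d = q
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c - a * d), 2 * (b * d + a * c)],
            [2 * (b * c + a * d), a * a - b * b + c * c - d * d, 2 * (c * d - a * b)],
            [2 * (b * d - a * c), 2 * (c * d + a * b), a * a - b * b - c * c + d * d],
        ]
    )


class TestKabsch:
    def test_identical_frames_have_zero_rmsd(self, rng):
        coords = rng.normal(size=(20, 3))
        f = StructureFrame(coords)
        result = kabsch_superpose(f, StructureFrame(coords.copy()))
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)

    def test_pure_translation_removed(self, rng):
        coords = rng.normal(size=(15, 3))
        shifted = StructureFrame(coords + np.array([1.0, 2.0, 3.0]))
        assert kabsch_superpose(shifted, StructureFrame(coords)).rmsd < 1e-12

    def test_matches_quaternion_oracle_with_noise(self, rng):
        for _ in range(100):
            n = rng.integers(4, 40)
            ref = rng.normal(size=(n, 3))
            mob = ref @ random_rotation(rng).T + rng.normal(0, 0.1, size=(n, 3))
            mob += rng.normal(size=3)
            got = kabsch_superpose(StructureFrame(mob), StructureFrame(ref)).rmsd
            assert abs(got - quaternion_rmsd(mob, ref)) < 1e-9

    def test_mass_weighting_matches_oracle(self, rng):
        n = 25
        ref = rng.normal(size=(n, 3))
        mob = ref + rng.normal(0, 0.2, size=(n, 3))
        w = rng.uniform(1, 16, size=n)
        got = kabsch_superpose(StructureFrame(mob, w), StructureFrame(ref, w)).rmsd
        assert abs(got - quaternion_rmsd(mob, ref, w)) < 1e-9

    def test_rotation_is_proper_even_for_reflected_input(self, rng):
        ref = rng.normal(size=(10, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        result = kabsch_superpose(StructureFrame(mirrored), StructureFrame(ref))
        assert np.linalg.det(result.rotation) == pytest.approx(1.0)

    def test_collinear_geometry_flagged_translation_only(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        result = kabsch_superpose(
            StructureFrame(line + 5.0), StructureFrame(line)
        )
        assert result.degenerate
        assert np.array_equal(result.rotation, np.eye(3))
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_atom_count_mismatch(self, rng):
        with pytest.raises(ContractError, match="mismatch"):
            kabsch_superpose(
                StructureFrame(rng.normal(size=(4, 3))),
                StructureFrame(rng.normal(size=(5, 3))),
            )

    def test_superposed_rmsd_never_exceeds_raw(self, rng):
        for _ in range(20):
            a = rng.normal(size=(12, 3))
            b = rng.normal(size=(12, 3))
            raw = math.sqrt((((a - a.mean(0)) - (b - b.mean(0))) ** 2).sum(1).mean())
            assert kabsch_superpose(StructureFrame(a), StructureFrame(b)).rmsd <= raw + 1e-12

    def test_symmetry(self, rng):
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        ab = kabsch_superpose(StructureFrame(a), StructureFrame(b)).rmsd
        ba = kabsch_superpose(StructureFrame(b), StructureFrame(a)).rmsd
        assert ab == pytest.approx(ba, abs=1e-12)


class TestRmsdSeries:
    def test_identical_frames_give_zero_series(self, rng):
        coords = rng.normal(size=(10, 3))
        traj = Trajectory(
            [StructureFrame(coords.copy()) for _ in range(5)], np.arange(5.0)
        )
        series = rmsd_series(traj, traj.frames[0])
        assert np.allclose(series.values, 0.0, atol=1e-12)

    def test_rigid_body_motion_removed(self):
        traj = generate_trajectory(
            TrajectorySpec(n_atoms=20, n_frames=10, fluctuation_sd=0.0,
                           rigid_motion=(3.0, 0.05), seed=7)
        )
        series = rmsd_series(traj, traj.frames[0])
        assert np.allclose(series.values, 0.0, atol=1e-9)

    def test_fluctuating_trajectory_mean_near_generator_target(self):
        sigma, n_atoms, n_frames = 0.05, 100, 400
        traj = generate_trajectory(
            TrajectorySpec(n_atoms=n_atoms, n_frames=n_frames,
                           fluctuation_sd=sigma, seed=11)
        )
        series = rmsd_series(traj, traj.frames[0])
        # frame-vs-frame jitter: both frames carry noise, superposition fits
        # 6 dof; expected RMSD ~ sigma * sqrt(6) for large N
        expected = sigma * math.sqrt(6.0)
        se = series.values[1:].std() / math.sqrt(n_frames - 1)
        assert abs(series.values[1:].mean() - expected) < max(3 * se, 0.05 * expected)


class TestRmsf:
    def test_static_trajectory_all_zero(self, rng):
        coords = rng.normal(size=(8, 3))
        traj = Trajectory([StructureFrame(coords.copy()) for _ in range(4)], np.arange(4.0))
        assert np.allclose(rmsf_per_atom(traj), 0.0, atol=1e-12)

    def test_single_oscillating_atom_closed_form(self):
        # one light atom alternates +/- d along x; the anchor cloud is made
        # heavy so the mass-weighted fit is pinned and the closed form
        # RMSF = d holds to high accuracy
        base = np.array(
            [[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10], [10, 10, 10], [5.0, 5, 5]]
        )
        masses = np.array([1e6, 1e6, 1e6, 1e6, 1e6, 1.0])
        d = 0.01
        frames = []
        for k in range(4):
            c = base.copy()
            c[5, 0] += d if k % 2 == 0 else -d
            frames.append(StructureFrame(c, masses.copy()))
        rmsf = rmsf_per_atom(Trajectory(frames, np.arange(4.0)))
        assert rmsf[5] == pytest.approx(d, rel=1e-4)
        assert np.all(rmsf[:5] < 1e-6)

    def test_isotropic_jitter_scales_as_sigma_root_three(self):
        sigma = 0.05
        traj = generate_trajectory(
            TrajectorySpec(n_atoms=100, n_frames=2000, fluctuation_sd=sigma, seed=3)
        )
        rmsf = rmsf_per_atom(traj)
        assert abs(rmsf.mean() - sigma * math.sqrt(3)) / (sigma * math.sqrt(3)) < 0.05

    def test_single_frame_rejected(self, rng):
        traj = Trajectory([StructureFrame(rng.normal(size=(5, 3)))], [0.0])
        with pytest.raises(ContractError):
            rmsf_per_atom(traj)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(StructureFrame([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_unit_masses_half_distance(self):
        f = StructureFrame([[0.0, 0, 0], [0, 0, 3.0]])
        assert radius_of_gyration(f) == pytest.approx(1.5)

    def test_cube_closed_form(self):
        a = 2.0
        corners = [
            [x, y, z] for x in (0, a) for y in (0, a) for z in (0, a)
        ]
        assert radius_of_gyration(StructureFrame(corners)) == pytest.approx(
            a * math.sqrt(3) / 2
        )

    @given(scale=st.floats(0.1, 10), shift=st.floats(-5, 5))
    @settings(max_examples=25)
    def test_invariance_and_scaling(self, scale, shift):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(12, 3))
        masses = rng.uniform(1, 12, size=12)
        base = radius_of_gyration(StructureFrame(coords, masses))
        rot = random_rotation(np.random.default_rng(1))
        moved = radius_of_gyration(StructureFrame(coords @ rot.T + shift, masses))
        scaled = radius_of_gyration(StructureFrame(coords * scale, masses))
        assert moved == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9)


def brute_force_hbonds(coords, donors, acceptors, criterion):
    found = set()
    for d, h in donors:
        for a in acceptors:
            if a in (d, h) or (d, a) in found:
                continue
            da = coords[a] - coords[d]
            dist = np.linalg.norm(da)
            if dist == 0 or dist > criterion.max_da_distance:
                continue
            dh = coords[h] - coords[d]
            cos = np.dot(dh, da) / (np.linalg.norm(dh) * dist)
            if math.degrees(math.acos(np.clip(cos, -1, 1))) <= criterion.max_angle:
                found.add((d, a))
    return len(found)


class TestHbonds:
    def test_ideal_geometry_counts_one(self):
        coords = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.28, 0, 0]])
        assert count_hbonds(StructureFrame(coords), [(0, 1)], [2]) == 1

    def test_distance_cut(self):
        coords = np.array([[0.0, 0, 0], [0.1, 0, 0], [0.40, 0, 0]])
        assert count_hbonds(StructureFrame(coords), [(0, 1)], [2]) == 0

    def test_angle_cut(self):
        # hydrogen perpendicular to the D->A axis: angle 90 degrees
        coords = np.array([[0.0, 0, 0], [0, 0.1, 0], [0.28, 0, 0]])
        assert count_hbonds(StructureFrame(coords), [(0, 1)], [2]) == 0

    def test_matches_brute_force_on_random_frames(self, rng):
        crit = HBondCriterion()
        for _ in range(50):
            n = int(rng.integers(6, 30))
            coords = rng.uniform(0, 1.0, size=(n, 3))
            donors = []
            for _ in range(rng.integers(1, 6)):
                d, h = rng.choice(n, size=2, replace=False)
                donors.append((int(d), int(h)))
            acceptors = rng.choice(n, size=rng.integers(1, 8), replace=False).tolist()
            got = count_hbonds(StructureFrame(coords), donors, acceptors, crit)
            assert got == brute_force_hbonds(coords, donors, acceptors, crit)

    def test_invalid_indices(self, rng):
        f = StructureFrame(rng.normal(size=(4, 3)))
        with pytest.raises(ContractError):
            count_hbonds(f, [(0, 0)], [2])
        with pytest.raises(ContractError):
            count_hbonds(f, [(0, 1)], [9])


class TestSeriesSummary:
    def test_constant_series(self):
        s = FrameSeries("other", np.arange(5.0), np.full(5, 3.3))
        stat = series_summary(s)
        assert stat.mean == 3.3 and stat.sd == 0.0 and stat.n == 5

    def test_small_series_population_sd(self):
        stat = series_summary(FrameSeries("other", np.arange(3.0), [1.0, 2.0, 3.0]))
        assert stat.mean == 2.0
        assert stat.sd == pytest.approx(math.sqrt(2.0 / 3.0))

    def test_equilibration_skip(self):
        s = FrameSeries("rmsd_nm", np.array([0.0, 10, 20, 30]), [9.0, 1, 1, 1])
        stat = series_summary(s, equilibration_skip=10.0)
        assert stat.mean == 1.0 and stat.n == 3

    def test_empty_after_skip(self):
        s = FrameSeries("other", np.array([0.0, 1.0]), [1.0, 2.0])
        with pytest.raises(ContractError):
            series_summary(s, equilibration_skip=100.0)

    def test_generated_noisy_series_mean_within_three_se(self, rng):
        mu, sd, n = 0.37, 0.03, 2000
        s = FrameSeries("rmsd_nm", np.arange(float(n)), rng.normal(mu, sd, n))
        stat = series_summary(s)
        assert abs(stat.mean - mu) < 3 * sd / math.sqrt(n)


class TestTextFormats:
    def test_xvg_round_trip(self, tmp_path):
        s = FrameSeries("rg_nm", np.array([0.0, 10.0, 20.0]), [2.1, 2.2, 2.15])
        path = write_xvg(s, tmp_path / "rg.xvg", title="radius of gyration")
        back = parse_xvg(path, "rg_nm")
        assert np.allclose(back.times, s.times)
        assert np.allclose(back.values, s.values)
        assert back.units == "nm"

    def test_xvg_comments_only_is_format_error(self, tmp_path):
        p = tmp_path / "c.xvg"
        p.write_text("# a comment\n@ title \"nothing\"\n")
        with pytest.raises(FormatError):
            parse_xvg(p)

    def test_xyz_round_trip(self, tmp_path, rng):
        traj = generate_trajectory(TrajectorySpec(n_atoms=5, n_frames=3, seed=2))
        path = write_xyz(traj, tmp_path / "t.xyz")
        back = read_xyz(path)
        assert back.n_frames == 3 and back.n_atoms == 5
        assert np.allclose(back.times, traj.times)
        for f1, f2 in zip(back.frames, traj.frames):
            assert np.allclose(f1.coordinates, f2.coordinates, atol=1e-6)

    def test_truncated_xyz(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("4\nt= 0 ps\nX 0 0 0\nX 1 1 1\n")
        with pytest.raises(FormatError):
            read_xyz(p)
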