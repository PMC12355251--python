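"""Superposition and trajectory-metric oracles and invariances."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hingeflex import (
    StructureError,
    Trajectory,
    classify_regions,
    interdomain_angle,
    kabsch_superpose,
    radius_of_gyration,
    rmsd_series,
    rmsf_per_residue,
    toy_domain_map,
)
from hingeflex.model_io import DomainMap, ParameterError, Structure


def horn_quaternion_rmsd(mobile, reference):
    """Independent closed-form optimal-superposition RMSD (Horn's
    quaternion method: largest eigenvalue of the 4x4 profile matrix)."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    M = a.T @ b
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K).max()
    n = a.shape[0]
    msd = (np.sum(a * a) + np.sum(b * b) - 2.0 * lam) / n
    return math.sqrt(max(msd, 0.0))


class TestKabsch:
    def test_identity_superposition(self, rng):
        pts = rng.normal(size=(10, 3))
        res = kabsch_superpose(pts, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-8)

    def test_rigid_transform_recovered(self, rng):
        pts = rng.normal(size=(12, 3))
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([5.0, -2.0, 1.0])
        res = kabsch_superpose(moved, pts)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("case", [0, 1, 2])
    def test_rmsd_matches_quaternion_oracle_on_4_point_sets(self, case):
        sets = [
            (np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0, 0, 1.0]]),
             np.array([[0.1, 0, 0], [1.4, 0.2, 0], [0, 1.8, 0.3],
                       [0.2, 0, 1.1]])),
            (np.array([[1.0, 1, 1], [2, 1, 1], [1, 3, 1], [1, 1, 2]]),
             np.array([[0.0, 0, 0], [0, 1.1, 0], [-2.9, 0, 0.2],
                       [0, 0.1, -1.2]])),
            (np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0], [1, 1, 5]]),
             np.array([[0.0, 0, 0], [2.8, 0.4, 0], [0.5, 3.9, 0],
                       [0.8, 1.2, 4.9]])),
        ]
        mob, ref = sets[case]
        res = kabsch_superpose(mob, ref)
        assert res.rmsd == pytest.approx(horn_quaternion_rmsd(mob, ref),
                                         abs=1e-6)

    def test_rmsd_symmetric_and_rigid_invariant(self, rng):
        a = rng.normal(size=(8, 3))
        b = a + rng.normal(scale=0.3, size=(8, 3))
        r_ab = kabsch_superpose(a, b).rmsd
        r_ba = kabsch_superpose(b, a).rmsd
        assert r_ab == pytest.approx(r_ba, abs=1e-9)
        R = Rotation.random(random_state=3).as_matrix()
        t = np.array([1.0, 2.0, -3.0])
        r_moved = kabsch_superpose(a @ R.T + t, b @ R.T + t).rmsd
        assert r_moved == pytest.approx(r_ab, abs=1e-9)

    def test_degenerate_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(StructureError, match="collinear"):
            kabsch_superpose(line, line)
        with pytest.raises(StructureError, match=">= 3"):
            kabsch_superpose(line[:2], line[:2])


class TestRMSDSeries:
    def _static_traj(self, structure, n=5):
        return Trajectory(topology=structure,
                          frames=np.stack([structure.coords] * n))

    def test_copies_of_reference_give_zero(self, open_structure):
        traj = self._static_traj(open_structure)
        assert np.allclose(rmsd_series(traj, open_structure), 0.0,
                           atol=1e-9)

    def test_translation_removed_by_alignment(self, open_structure):
        shifted = open_structure.with_coords(open_structure.coords
                                             + [5.0, 0.0, 0.0])
        traj = self._static_traj(open_structure)
        assert np.allclose(rmsd_series(traj, shifted), 0.0, atol=1e-9)

    def test_single_displaced_atom_quadratic_mean(self):
        """One atom of 100 displaced by 2 A, aligned on the 99 fixed ones:
        rmsd over all 100 = 2/sqrt(100) = 0.2 A."""
        rng = np.random.default_rng(5)
        coords = rng.normal(scale=10.0, size=(100, 3))
        ref = Structure(atom_names=tuple("CA" for _ in range(100)),
                        res_names=tuple("GLY" for _ in range(100)),
                        res_ids=np.arange(1, 101),
                        coords=coords, masses=np.full(100, 12.0))
        moved = coords.copy()
        moved[0] += [2.0, 0.0, 0.0]
        traj = Trajectory(topology=ref, frames=moved[None])
        out = rmsd_series(traj, ref, align_selection=np.arange(1, 100),
                          measure_selection=np.arange(100))
        assert out[0] == pytest.approx(0.2, rel=1e-6)


class TestRMSF:
    def test_static_trajectory_zero(self, open_structure):
        traj = Trajectory(topology=open_structure,
                          frames=np.stack([open_structure.coords] * 10))
        _, vals = rmsf_per_residue(traj)
        assert np.allclose(vals, 0.0, atol=1e-9)

    def test_single_oscillating_residue_gives_d(self):
        """One atom alternating +/-d about its mean along the radial
        direction through the centroid (so the alignment induces no
        rotation): its RMSF is d(1 - 1/n) exactly — the oscillation minus
        the centroid shift it causes — and the rest pick up only d/n."""
        rng = np.random.default_rng(8)
        n, d = 40, 0.5
        base = rng.normal(scale=50.0, size=(n, 3))
        base -= base.mean(axis=0)
        base[0] = [80.0, 0.0, 0.0]  # on +x axis: x-oscillation is radial
        base -= base.mean(axis=0)
        base[0, 1:] = 0.0
        frames = np.stack([base.copy() for _ in range(20)])
        frames[::2, 0, 0] += d
        frames[1::2, 0, 0] -= d
        s = Structure(atom_names=tuple("CA" for _ in range(n)),
                      res_names=tuple("GLY" for _ in range(n)),
                      res_ids=np.arange(1, n + 1),
                      coords=base, masses=np.full(n, 12.0))
        _, vals = rmsf_per_residue(Trajectory(topology=s, frames=frames))
        assert vals[0] == pytest.approx(d * (1 - 1 / n), rel=1e-2)
        assert vals[1:].max() < 2 * d / n

    def test_concatenated_identical_replicas_equal_single(self, short_traj):
        _, single = rmsf_per_residue(short_traj)
        _, triple = rmsf_per_residue([short_traj, short_traj, short_traj])
        assert np.allclose(single, triple, atol=1e-8)

    def test_offset_leaving_no_frames_rejected(self, short_traj):
        with pytest.raises(ParameterError, match="offset"):
            rmsf_per_residue(short_traj,
                             equilibration_offset=short_traj.n_frames)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_points_two_angstrom_apart(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        assert radius_of_gyration(pts) == pytest.approx(1.0)

    def test_square_corners(self):
        pts = np.array([[0.0, 0, 0], [2, 0, 0], [0, 2, 0], [2, 2, 0]])
        assert radius_of_gyration(pts) == pytest.approx(math.sqrt(2.0))

    def test_rigid_invariance_and_linear_scaling(self, rng):
        pts = rng.normal(size=(30, 3))
        rg = radius_of_gyration(pts)
        R = Rotation.random(random_state=1).as_matrix()
        assert radius_of_gyration(pts @ R.T + 7.0) == pytest.approx(rg)
        assert radius_of_gyration(3.0 * pts) == pytest.approx(3.0 * rg)

    def test_zero_weights_rejected(self):
        with pytest.raises(ParameterError, match="weight"):
            radius_of_gyration(np.zeros((2, 3)), weights=[0.0, 0.0])


class TestInterdomainAngle:
    def _three_center_structure(self, c1, c2, c3):
        coords = np.vstack([c1, c2, c3])
        return Structure(atom_names=("CA", "CA", "CA"),
                         res_names=("GLY", "GLY", "GLY"),
                         res_ids=np.array([1, 2, 3]),
                         coords=coords, masses=np.full(3, 12.0)), \
            DomainMap(domains={"I": (1, 1), "II": (2, 2), "III": (3, 3)})

    @pytest.mark.parametrize("c1,c3,expected", [
        ([-1, 0, 0], [1, 0, 0], 180.0),
        ([1, 0, 0], [0, 1, 0], 90.0),
        ([1, 0, 0], [0.5, math.sqrt(3) / 2, 0], 60.0),
    ])
    def test_geometry_cases(self, c1, c3, expected):
        s, dmap = self._three_center_structure(c1, [0, 0, 0], c3)
        assert interdomain_angle(s, dmap) == pytest.approx(expected)

    def test_coincident_centers_rejected(self):
        s, dmap = self._three_center_structure([0, 0, 0], [0, 0, 0],
                                               [1, 0, 0])
        with pytest.raises(StructureError, match="coincident"):
            interdomain_angle(s, dmap)


class TestClassifyRegions:
    def _flat_rmsf(self, dmap, value=1.0):
        ids = dmap.all_residues()
        return ids, np.full(ids.size, value)

    def test_zero_delta_all_comparable(self, small_spec):
        dmap = toy_domain_map(small_spec)
        wt = self._flat_rmsf(dmap)
        for v in classify_regions(wt, wt, dmap):
            assert v.symbol == "~"

    def test_domain_I_raised_by_one_and_a_half(self, small_spec):
        dmap = toy_domain_map(small_spec)
        ids, wt = self._flat_rmsf(dmap)
        var = wt.copy()
        lo, hi = dmap.domains["I"]
        var[(ids >= lo) & (ids <= hi)] += 1.5
        verdicts = {v.region: v.symbol
                    for v in classify_regions((ids, var), (ids, wt), dmap)}
        assert verdicts["I"] == "up"
        assert all(s == "~" for r, s in verdicts.items() if r != "I")

    def test_mixed_rise_and_fall_is_x(self, small_spec):
        dmap = toy_domain_map(small_spec)
        ids, wt = self._flat_rmsf(dmap, value=3.0)
        var = wt.copy()
        lo, hi = dmap.domains["II"]
        sel = np.nonzero((ids >= lo) & (ids <= hi))[0]
        var[sel[0]] += 2.0
        var[sel[1]] -= 2.0
        verdicts = {v.region: v.symbol
                    for v in classify_regions((ids, var), (ids, wt), dmap)}
        assert verdicts["II"] == "x"

    def test_antisymmetry_under_swap(self, small_spec, rng):
        dmap = toy_domain_map(small_spec)
        ids = dmap.all_residues()
        wt = 2.0 + rng.uniform(0, 0.2, ids.size)
        var = wt + rng.choice([0.0, 1.4, -1.4], size=ids.size,
                              p=[0.8, 0.1, 0.1])
        fwd = classify_regions((ids, var), (ids, wt), dmap)
        rev = classify_regions((ids, wt), (ids, var), dmap)
        flip = {"up": "down", "down": "up", "~": "~", "x": "x"}
        for a, b in zip(fwd, rev):
            assert b.symbol == flip[a.symbol]

    def test_coverage_gap_rejected(self, small_spec):
        dmap = toy_domain_map(small_spec)
        ids = dmap.all_residues()[:-3]
        vals = np.ones(ids.size)
        with pytest.raises(StructureError, match="no RMSF"):
            classify_regions((ids, vals), (ids, vals), dmap)
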