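"""Debye profiles, Guinier/Kratky/P(r) analysis, conformer pools,
multistate ensemble fitting and domain displacement geometry."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hingeflex import (
    ConformerPool,
    ParameterError,
    SAXSProfile,
    StructureError,
    debye_profile,
    domain_displacement,
    generate_pool,
    guinier_fit,
    kratky_dimensionless,
    multistate_fit,
    pr_from_model,
    radius_of_gyration,
    synthesize_saxs_profile,
)
from hingeflex.model_io import Structure


def _beads(coords):
    n = len(coords)
    return Structure(atom_names=tuple("CA" for _ in range(n)),
                     res_names=tuple("GLY" for _ in range(n)),
                     res_ids=np.arange(1, n + 1),
                     coords=np.asarray(coords, dtype=float),
                     masses=np.full(n, 12.0))


def ideal_guinier_profile(rg, i0=100.0, qmax=0.3, n=300, sigma_frac=None):
    q = np.linspace(qmax / n, qmax, n)
    I = i0 * np.exp(-(q * rg) ** 2 / 3.0)
    sigma = sigma_frac * I if sigma_frac else None
    return SAXSProfile(q=q, I=I, sigma=sigma)


class TestDebyeProfile:
    def test_single_bead_flat_unity(self):
        p = debye_profile(_beads([[0.0, 0, 0]]))
        assert np.allclose(p.I, 1.0)

    def test_two_beads_i0_and_sinc_zero(self):
        d = 5.0
        q = np.array([1e-6, math.pi / d])
        p = debye_profile(_beads([[0.0, 0, 0], [d, 0, 0]]), q_grid=q)
        assert p.I[0] == pytest.approx(4.0, rel=1e-9)
        assert p.I[1] == pytest.approx(2.0, rel=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.normal(scale=10.0, size=(50, 3))
        f = rng.uniform(0.5, 2.0, 50)
        q = np.linspace(0.01, 0.4, 25)
        p = debye_profile(_beads(coords), q_grid=q, form_factors=f)
        oracle = np.zeros_like(q)
        for a, qv in enumerate(q):
            total = 0.0
            for i in range(50):
                for j in range(50):
                    r = np.linalg.norm(coords[i] - coords[j])
                    x = qv * r
                    total += f[i] * f[j] * (math.sin(x) / x if x > 0 else 1.0)
            oracle[a] = total
        assert np.allclose(p.I, oracle, rtol=1e-10)

    def test_i_zero_is_squared_total_form_factor(self, rng):
        coords = rng.normal(size=(20, 3))
        f = rng.uniform(0.5, 1.5, 20)
        p = debye_profile(_beads(coords), q_grid=np.array([0.0, 0.1]),
                          form_factors=f)
        assert p.I[0] == pytest.approx(f.sum() ** 2, rel=1e-12)


class TestGuinierFit:
    def test_recovers_generative_rg(self):
        i0, rg = 100.0, 28.4
        prof = ideal_guinier_profile(rg, i0)
        fit_i0, fit_rg, _ = guinier_fit(prof)
        assert fit_rg == pytest.approx(rg, rel=1e-3)
        assert fit_i0 == pytest.approx(i0, rel=1e-3)

    def test_flat_profile_no_guinier_regime(self):
        q = np.linspace(0.001, 0.3, 100)
        with pytest.raises(ParameterError, match="Guinier"):
            guinier_fit(SAXSProfile(q=q, I=np.full(100, 5.0)))

    def test_debye_rg_consistent_with_coordinates(self, open_structure):
        prof = debye_profile(open_structure,
                             q_grid=np.linspace(0.002, 0.2, 200))
        _, fit_rg, _ = guinier_fit(prof)
        coord_rg = radius_of_gyration(open_structure.coords)
        assert fit_rg == pytest.approx(coord_rg, rel=0.02)

    def test_window_respects_qmax_rule(self):
        prof = ideal_guinier_profile(25.0)
        _, rg, (lo, hi) = guinier_fit(prof)
        assert prof.q[hi - 1] <= 1.0 / rg * 1.05


class TestKratky:
    def test_ideal_globular_peak(self):
        prof = ideal_guinier_profile(20.0, qmax=0.2, n=1200)
        i0, rg, _ = guinier_fit(prof)
        _, peak_x, peak_y = kratky_dimensionless(prof, rg, i0)
        assert peak_x == pytest.approx(math.sqrt(3.0), abs=0.01)
        assert peak_y == pytest.approx(3.0 / math.e, abs=0.005)
        assert round(peak_y, 1) == 1.1

    def test_flat_profile_peaks_at_edge_with_warning(self):
        q = np.linspace(0.001, 0.3, 500)
        prof = SAXSProfile(q=q, I=np.full(500, 7.0))
        with pytest.warns(UserWarning, match="rising"):
            _, peak_x, _ = kratky_dimensionless(prof, rg=10.0, i0=7.0)
        assert peak_x == pytest.approx(3.0, abs=0.05)

    def test_flexible_mixture_plateaus_above_globular_reference(
            self, small_spec, small_map, open_structure):
        """A mixture of compact and extended hinge conformers keeps the
        dimensionless Kratky transform above the globular 1.1 level out
        to qRg = 3 (plateau) instead of decaying."""
        pool = generate_pool(open_structure, small_map, n_conformers=20,
                             angle_range=70.0, seed=5,
                             q_grid=np.linspace(0.002, 0.5, 400))
        idx = np.argsort(pool.member_rg)
        picks = [idx[0], idx[len(idx) // 2], idx[-1]]
        comps = [SAXSProfile(q=pool.q_grid, I=pool.profiles[i])
                 for i in picks]
        mix = synthesize_saxs_profile(comps, [0.3, 0.3, 0.4])
        i0, rg, _ = guinier_fit(mix)
        with pytest.warns(UserWarning, match="rising"):
            curve, _, _ = kratky_dimensionless(mix, rg, i0)
        at3 = curve[curve["qRg"] <= 3.0]["kratky"].iloc[-1]
        globular = ideal_guinier_profile(rg, i0, qmax=3.2 / rg, n=400)
        gcurve, _, _ = kratky_dimensionless(globular, rg, i0)
        g_at3 = gcurve[gcurve["qRg"] <= 3.0]["kratky"].iloc[-1]
        assert at3 > g_at3

    def test_coarse_grid_warns(self):
        q = np.linspace(0.02, 0.3, 10)
        prof = SAXSProfile(q=q, I=np.exp(-(q * 20.0) ** 2 / 3))
        with pytest.warns(UserWarning, match="resolution"):
            kratky_dimensionless(prof, rg=20.0, i0=1.0)


class TestPrFromModel:
    def test_two_beads_single_bin(self):
        table, dmax, _ = pr_from_model(_beads([[0.0, 0, 0], [10.0, 0, 0]]),
                                       n_bins=20)
        assert dmax == pytest.approx(10.0)
        occupied = table[table["P"] > 0]
        assert len(occupied) == 1
        assert occupied["r"].iloc[0] == pytest.approx(10.0, abs=0.5)

    def test_three_collinear_beads_hand_enumeration(self):
        table, dmax, _ = pr_from_model(
            _beads([[0.0, 0, 0], [5.0, 0, 0], [10.0, 0, 0]]), n_bins=10)
        assert dmax == pytest.approx(10.0)
        # pairs: (0,5), (5,10) at r=5 weight 2; (0,10) at r=10 weight 1
        # (r=5 lands in the half-open bin [5,6), r=10 in the last bin)
        w5 = table[np.isclose(table["r"], 5.5)]["P"].sum()
        w10 = table[np.isclose(table["r"], 9.5)]["P"].sum()
        assert w5 == pytest.approx(2.0)
        assert w10 == pytest.approx(1.0)

    def test_rg_matches_coordinate_rg_within_binning(self, open_structure):
        _, _, pr_rg = pr_from_model(open_structure, n_bins=200)
        coord_rg = radius_of_gyration(open_structure.coords)
        assert pr_rg == pytest.approx(coord_rg, rel=5e-3)

    def test_single_atom_rejected(self):
        with pytest.raises(ParameterError, match="two atoms"):
            pr_from_model(_beads([[0.0, 0, 0]]))


class TestGeneratePool:
    def test_zero_angle_range_reproduces_input(self, open_structure,
                                               small_map):
        pool = generate_pool(open_structure, small_map, n_conformers=5,
                             angle_range=0.0, seed=2)
        for c in pool.conformers:
            assert np.allclose(c.coords, open_structure.coords, atol=1e-9)

    def test_same_seed_identical_pool(self, open_structure, small_map):
        a = generate_pool(open_structure, small_map, 10, 40.0, seed=9)
        b = generate_pool(open_structure, small_map, 10, 40.0, seed=9)
        for ca, cb in zip(a.conformers, b.conformers):
            assert np.array_equal(ca.coords, cb.coords)

    def test_rg_spread_spans_compact_to_extended(self, open_structure,
                                                 small_map):
        pool = generate_pool(open_structure, small_map, n_conformers=60,
                             angle_range=70.0, seed=4)
        rgs = np.array(pool.member_rg)
        base = radius_of_gyration(open_structure.coords)
        assert rgs.min() < base - 1.0
        assert rgs.max() - rgs.min() > 3.0


class TestMultistateFit:
    def _pool(self, open_structure, small_map, n=25):
        return generate_pool(open_structure, small_map, n_conformers=n,
                             angle_range=60.0, seed=8)

    def test_single_member_profile_recovered(self, open_structure,
                                             small_map):
        pool = self._pool(open_structure, small_map)
        target = SAXSProfile(q=pool.q_grid, I=pool.profiles[7],
                             sigma=0.01 * pool.profiles[7])
        fits = multistate_fit(target, pool, n_states=(1,))
        best = fits[1][0]
        assert best.members == (7,)
        assert best.weights[0] == pytest.approx(1.0, abs=1e-9)
        assert best.chi == pytest.approx(0.0, abs=1e-8)

    def test_noise_free_two_state_exact_recovery(self, open_structure,
                                                 small_map):
        pool = self._pool(open_structure, small_map)
        idx = np.argsort(pool.member_rg)
        m1, m2 = int(idx[2]), int(idx[-3])
        mix = 0.3 * pool.profiles[m1] + 0.7 * pool.profiles[m2]
        target = SAXSProfile(q=pool.q_grid, I=mix, sigma=1e-4 * mix)
        fits = multistate_fit(target, pool, n_states=(2,))
        best = fits[2][0]
        assert set(best.members) == {m1, m2}
        w = dict(zip(best.members, best.weights))
        assert w[m1] == pytest.approx(0.3, abs=1e-6)
        assert w[m2] == pytest.approx(0.7, abs=1e-6)

    def test_chi_non_increasing_in_n(self, open_structure, small_map):
        pool = self._pool(open_structure, small_map)
        idx = np.argsort(pool.member_rg)
        mix = (0.2 * pool.profiles[idx[1]] + 0.5 * pool.profiles[idx[12]]
               + 0.3 * pool.profiles[idx[-2]])
        target = SAXSProfile(q=pool.q_grid, I=mix, sigma=0.02 * mix)
        fits = multistate_fit(target, pool, n_states=(1, 2, 3))
        chis = [fits[n][0].chi for n in (1, 2, 3)]
        assert chis[0] >= chis[1] - 1e-12
        assert chis[1] >= chis[2] - 1e-12

    def test_missing_sigma_rejected(self, open_structure, small_map):
        pool = self._pool(open_structure, small_map, n=5)
        target = SAXSProfile(q=pool.q_grid, I=pool.profiles[0])
        with pytest.raises(ParameterError, match="sigma"):
            multistate_fit(target, pool, n_states=(1,))

    def test_greedy_branch_finds_planted_pair(self, open_structure,
                                              small_map, monkeypatch):
        import hingeflex.saxs_suite as ss
        pool = self._pool(open_structure, small_map, n=30)
        idx = np.argsort(pool.member_rg)
        m1, m2 = int(idx[0]), int(idx[-1])
        mix = 0.4 * pool.profiles[m1] + 0.6 * pool.profiles[m2]
        target = SAXSProfile(q=pool.q_grid, I=mix, sigma=1e-3 * mix)
        monkeypatch.setattr(ss, "EXHAUSTIVE_LIMIT", 10)  # force greedy
        fits = multistate_fit(target, pool, n_states=(2,))
        best = fits[2][0]
        assert set(best.members) == {m1, m2}
        w = dict(zip(best.members, best.weights))
        assert w[m1] == pytest.approx(0.4, abs=1e-6)


class TestDomainDisplacement:
    def test_identity_gives_zero(self, open_structure, small_map):
        rep = domain_displacement(open_structure, open_structure, small_map)
        assert all(abs(a) < 1e-6 for a in rep.rotations_deg.values())
        assert all(d < 1e-6 for d in rep.displacements.values())

    def test_constructed_30_degree_rotation_recovered(self, open_structure,
                                                      small_map):
        from hingeflex.saxs_suite import _hinge_pivot
        pivot = _hinge_pivot(open_structure, small_map, "I-II")
        idx = small_map.domain_atom_indices(open_structure, "I")
        R = Rotation.from_rotvec(np.radians(30.0) * np.array([0, 0, 1.0]))
        coords = open_structure.coords.copy()
        coords[idx] = (coords[idx] - pivot) @ R.as_matrix().T + pivot
        conf = open_structure.with_coords(coords)
        rep = domain_displacement(conf, open_structure, small_map)
        assert rep.rotations_deg["I"] == pytest.approx(30.0, abs=1e-6)
        assert rep.rotations_deg["III"] == pytest.approx(0.0, abs=1e-6)

    def test_global_rigid_motion_removed(self, open_structure, small_map):
        R = Rotation.random(random_state=6).as_matrix()
        moved = open_structure.with_coords(
            open_structure.coords @ R.T + [4.0, 5.0, -6.0])
        rep = domain_displacement(moved, open_structure, small_map)
        assert all(abs(a) < 1e-6 for a in rep.rotations_deg.values())
        assert all(d < 1e-6 for d in rep.displacements.values())
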