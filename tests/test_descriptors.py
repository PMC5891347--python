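"""Geometric descriptors: distances, helix axes, fluctuations, shells."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cypdyn.descriptors import (
    BFACTOR_PER_MSF,
    HelixAxis,
    coordination_shell_profile,
    coordination_shell_radius,
    domain_average_bfactor,
    helix_axis,
    interdomain_distance,
    interdomain_distance_series,
    interhelix_angle,
    rmsf,
    salt_bridge_distance,
    salt_bridge_series,
)
from cypdyn.structio import Structure, StructureError, Trajectory, select_calpha
from cypdyn.synthetic import (
    ACID_CENTROID_OFFSET,
    BASE_N_OFFSET,
    SyntheticSpec,
    build_toy_protein,
    ideal_helix,
)

from conftest import make_chain, random_rotation


class TestInterdomainDistance:
    def test_two_single_atom_domains(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 10.0]])
        assert interdomain_distance(coords, [0], [1]) == pytest.approx(10.0)

    def test_matches_explicit_centroid_oracle(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(scale=20, size=(100, 3))
        a, b = np.arange(50), np.arange(50, 100)
        got = interdomain_distance(coords, a, b)
        ca = coords[a].sum(axis=0) / 50
        cb = coords[b].sum(axis=0) / 50
        assert got == pytest.approx(np.linalg.norm(ca - cb), abs=1e-10)

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError, match="at least one atom"):
            interdomain_distance(np.zeros((3, 3)), [], [0])

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_invariant_under_rigid_transforms(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=10, size=(20, 3))
        a, b = np.arange(10), np.arange(10, 20)
        d0 = interdomain_distance(coords, a, b)
        moved = coords @ random_rotation(rng).T + rng.normal(scale=50, size=3)
        assert interdomain_distance(moved, a, b) == pytest.approx(d0, abs=1e-8)


class TestSaltBridgeDistance:
    def _structure(self, names, resids, coords):
        n = len(names)
        return Structure(
            atom_names=np.array(names),
            resids=np.array(resids),
            resnames=np.full(n, "XXX"),
            chains=np.full(n, "A"),
            elements=np.array([nm[0] for nm in names]),
            coords=np.array(coords, dtype=float),
        )

    def test_single_pair(self):
        s = self._structure(["OD1", "NZ"], [1, 2], [[0, 0, 0], [3, 4, 0]])
        assert salt_bridge_distance(s, s.coords, 1, 2) == pytest.approx(5.0)

    def test_oxygen_pair_center_of_mass(self):
        s = self._structure(
            ["OD1", "OD2", "NZ"], [1, 1, 2],
            [[1, 0, 0], [-1, 0, 0], [0, 0, 3]],
        )
        assert salt_bridge_distance(s, s.coords, 1, 2) == pytest.approx(3.0)

    def test_missing_side_chain_names_residue(self):
        s = self._structure(["CA", "NZ"], [1, 2], [[0, 0, 0], [1, 1, 1]])
        with pytest.raises(StructureError, match="residue 1"):
            salt_bridge_distance(s, s.coords, 1, 2)

    def test_synthetic_proxy_geometry_is_analytic(self):
        spec = SyntheticSpec(n_domain1=24, n_domain2=24, n_linker=6, seed=0)
        s = build_toy_protein(spec)
        y = np.array([0.0, 1.0, 0.0])
        for acid, base in spec.salt_bridge_pairs:
            ca_a = s.coords[(s.resids == acid) & (s.atom_names == "CA")][0]
            ca_b = s.coords[(s.resids == base) & (s.atom_names == "CA")][0]
            expected = np.linalg.norm(
                (ca_a + ACID_CENTROID_OFFSET * y) - (ca_b + BASE_N_OFFSET * y)
            )
            got = salt_bridge_distance(s, s.coords, acid, base)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_series_over_trajectory(self, small_spec, two_state):
        traj, _ = two_state
        acid, base = small_spec.salt_bridge_pairs[0]
        series = salt_bridge_series(traj, acid, base)
        assert len(series) == traj.n_frames
        assert np.all(series.values > 0)


class TestHelixAxis:
    def test_ideal_helix_axis_along_z(self):
        # long enough that the finite-length O(1/n) tilt of the positional
        # PC1 falls below a degree
        pts = ideal_helix(36, np.zeros(3))
        axis = helix_axis(pts, np.arange(36))
        angle = np.degrees(np.arccos(np.clip(axis.vector @ [0, 0, 1], -1, 1)))
        assert angle <= 1.0

    def test_reversed_residue_order_gives_same_axis(self):
        pts = ideal_helix(15, np.zeros(3))
        fwd = helix_axis(pts, np.arange(15))
        rev = helix_axis(pts[::-1].copy(), np.arange(15))
        # N→C canonicalisation flips the reversed chain's axis back
        np.testing.assert_allclose(rev.vector, -fwd.vector, atol=1e-9)

    def test_bent_helix_matches_power_iteration_oracle(self):
        pts = ideal_helix(20, np.zeros(3))
        pts[10:] = pts[10:] @ random_rotation(np.random.default_rng(1)).T
        axis = helix_axis(pts, np.arange(20))
        d = pts - pts.mean(axis=0)
        cov = d.T @ d / len(pts)
        v = np.ones(3)
        for _ in range(500):
            v = cov @ v
            v /= np.linalg.norm(v)
        assert abs(abs(v @ axis.vector) - 1.0) <= 1e-8

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError, match="4 residues"):
            helix_axis(np.zeros((3, 3)), np.arange(3))

    def test_degenerate_geometry_warns(self):
        theta = np.linspace(0, 2 * np.pi, 30, endpoint=False)
        ring = np.column_stack(
            [np.cos(theta), np.sin(theta), 1e-6 * np.sin(3 * theta)])
        with pytest.warns(UserWarning, match="ill-defined"):
            helix_axis(ring, np.arange(30))


class TestInterhelixAngle:
    def _axis(self, v):
        return HelixAxis(vector=np.asarray(v, float), anchor=np.zeros(3))

    def test_parallel_axes(self):
        assert interhelix_angle(self._axis([0, 0, 1]), self._axis([0, 0, 1])) == 0.0

    def test_orthogonal_axes(self):
        a = self._axis([1, 0, 0])
        b = self._axis([0, 1, 0])
        assert interhelix_angle(a, b) == pytest.approx(90.0)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = self._axis(rng.normal(size=3))
            b = self._axis(rng.normal(size=3))
            t1 = interhelix_angle(a, b)
            t2 = interhelix_angle(b, a)
            assert t1 == pytest.approx(t2, abs=1e-10)
            assert 0.0 <= t1 < 180.0

    def test_matches_arccos_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            va = rng.normal(size=3)
            vb = rng.normal(size=3)
            va /= np.linalg.norm(va)
            vb /= np.linalg.norm(vb)
            got = interhelix_angle(self._axis(va), self._axis(vb))
            want = np.degrees(np.arccos(np.clip(va @ vb, -1.0, 1.0)))
            assert got == pytest.approx(want, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero length"):
            interhelix_angle(self._axis([0, 0, 0]), self._axis([0, 0, 1]))


class TestRmsf:
    def test_two_frame_closed_form(self):
        s = make_chain(3)
        d = 0.9
        c0, c1 = s.coords.copy(), s.coords.copy()
        c0[:, 0] += d
        c1[:, 0] -= d
        traj = Trajectory(structure=s, coords=np.stack([c0, c1]), aligned=True)
        profile = rmsf(traj, np.arange(3))
        np.testing.assert_allclose(profile.rmsf, d, atol=1e-12)

    def test_bfactor_relation(self):
        s = make_chain(2)
        c0, c1 = s.coords.copy(), s.coords.copy()
        c0[:, 1] += 1.0
        c1[:, 1] -= 1.0
        traj = Trajectory(structure=s, coords=np.stack([c0, c1]), aligned=True)
        profile = rmsf(traj, np.arange(2))
        np.testing.assert_allclose(profile.bfactor, 8 * np.pi ** 2 / 3, atol=1e-9)
        assert BFACTOR_PER_MSF == pytest.approx(26.3189, abs=1e-3)

    def test_unaligned_trajectory_warns(self):
        rng = np.random.default_rng(5)
        s = make_chain(4)
        coords = s.coords[None] + rng.normal(size=(3, 4, 3))
        traj = Trajectory(structure=s, coords=coords)
        with pytest.warns(UserWarning, match="not flagged as aligned"):
            rmsf(traj, np.arange(4))


class TestDomainAverage:
    def _profile(self, rmsf_values):
        from cypdyn.descriptors import FluctuationProfile

        return FluctuationProfile(
            resids=np.arange(1, len(rmsf_values) + 1),
            rmsf=np.asarray(rmsf_values, float),
        )

    def test_uniform(self):
        assert domain_average_bfactor(self._profile([0.5] * 6), (1, 6)) == 0.5

    def test_single_residue_domain(self):
        p = self._profile([0.2, 0.9, 0.4])
        assert domain_average_bfactor(p, (2, 2)) == pytest.approx(0.9)

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError, match="no residues"):
            domain_average_bfactor(self._profile([1.0]), (5, 9))


class TestCoordinationShell:
    def test_two_atoms(self):
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        prof = coordination_shell_radius(coords, [0, 1], np.array([1, 2]), cutoff=6.0)
        np.testing.assert_allclose(prof.radius, 5.0)
        assert prof.average == pytest.approx(5.0)

    def test_cubic_lattice_interior(self):
        a = 3.0
        ax = np.arange(5)
        gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
        coords = a * np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float)
        n = len(coords)
        prof = coordination_shell_radius(coords, np.arange(n), np.arange(1, n + 1),
                                         cutoff=1.1 * a)
        interior = prof.n_neighbors == 6
        assert interior.sum() == 27  # 3x3x3 inner cube
        np.testing.assert_allclose(prof.radius[interior], a, atol=1e-10)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(6)
        coords = rng.normal(scale=8, size=(40, 3))
        cutoff = 7.5
        prof = coordination_shell_radius(coords, np.arange(40),
                                         np.arange(1, 41), cutoff)
        for i in range(40):
            sq, n = 0.0, 0
            for j in range(40):
                if i == j:
                    continue
                rij = np.linalg.norm(coords[i] - coords[j])
                if rij <= cutoff:
                    sq += rij ** 2
                    n += 1
            if n == 0:
                assert np.isnan(prof.radius[i])
            else:
                assert prof.radius[i] == pytest.approx(np.sqrt(sq / n), abs=1e-10)

    def test_isolated_residue_excluded_from_average(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [100.0, 0, 0]])
        prof = coordination_shell_radius(coords, [0, 1, 2], np.array([1, 2, 3]), 5.0)
        assert prof.n_neighbors[2] == 0
        assert np.isnan(prof.radius[2])
        assert prof.average == pytest.approx(1.0)

    def test_radius_bounded_by_cutoff_and_monotone_in_cutoff(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(scale=6, size=(30, 3))
        prev = 0.0
        for cutoff in (4.0, 6.0, 8.0, 12.0):
            prof = coordination_shell_radius(coords, np.arange(30),
                                             np.arange(1, 31), cutoff)
            ok = prof.n_neighbors > 0
            assert np.all(prof.radius[ok] <= cutoff)
            assert prof.average >= prev - 1e-12
            prev = prof.average

    def test_compact_ensemble_has_larger_average_when_cutoff_spans_gap(self):
        from cypdyn.synthetic import make_basin

        spec = SyntheticSpec(seed=0)
        ext = build_toy_protein(spec)
        comp = make_basin(ext, spec.compact_distance, spec.domain1_range,
                          spec.domain2_range, spec.linker_range)
        sel = select_calpha(ext, (1, spec.n_residues))
        cutoff = 28.0  # exceeds the closest interdomain approach when compact
        avg_ext = coordination_shell_radius(ext.coords, sel, ext.resids, cutoff).average
        avg_comp = coordination_shell_radius(comp.coords, sel, comp.resids, cutoff).average
        assert avg_comp >= avg_ext

    def test_per_frame_and_mean_structure_modes(self, two_state):
        traj, _ = two_state
        sel = select_calpha(traj.structure, (1, 54))
        per_frame = coordination_shell_profile(traj, sel, cutoff=10.0)
        on_mean = coordination_shell_profile(traj, sel, cutoff=10.0, per_frame=False)
        assert per_frame.radius.shape == on_mean.radius.shape
        assert np.isfinite(per_frame.average)


class TestSeriesOnSyntheticData:
    def test_per_basin_means_recover_generator_distances(self, small_spec, two_state):
        traj, truth = two_state
        series = interdomain_distance_series(
            traj, small_spec.domain1_range, small_spec.domain2_range)
        for label, target in (("extended", small_spec.extended_distance),
                              ("compact", small_spec.compact_distance)):
            vals = series.values[truth.labels == label]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            # noise shifts the expected centroid distance upward by
            # O(sigma^2/d); allow that bias plus 3 standard errors
            bias = 3 * small_spec.noise_sigma ** 2 / target
            assert abs(vals.mean() - target) <= 3 * se + bias
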