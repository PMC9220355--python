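"""Hydration tests: RDF normalization, shell integration and detection,
superposition against a quaternion oracle, and greedy clustering against a
naive oracle."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cuprobind import hydration as hy
from cuprobind import synthetic_data as sd

from oracles import greedy_cluster, quaternion_rmsd


def _single_water_frames(distance=2.07, n_frames=50, seed=0):
    """Cu at origin, one water rigidly fixed at the given distance."""
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords = np.array([[0.0, 0.0, 0.0], direction * distance])
        frames.append(hy.Frame(
            coords=coords,
            elements=np.array(["Cu", "O"], dtype=object),
            roles=np.array([hy.ROLE_COPPER, hy.ROLE_WATER_O], dtype=object),
            box=None,
        ))
    return frames


class TestRadialDistribution:
    def test_ideal_gas_is_flat_at_one(self):
        truth = sd.gen_ideal_gas_frames(1, n_frames=500)
        profile = hy.radial_distribution(truth.frames)
        mask = (profile.r >= 4.0) & (profile.r <= 8.0)
        assert abs(profile.g[mask].mean() - 1.0) <= 0.05

    def test_single_fixed_water_mass_in_one_bin(self):
        frames = _single_water_frames()
        rho = 1.0 / (4.0 / 3.0 * np.pi * 8.0**3)
        profile = hy.radial_distribution(frames, rho=rho)
        nonzero = np.flatnonzero(profile.g)
        assert len(nonzero) == 1
        lo = profile.r[nonzero[0]] - profile.dr / 2
        hi = profile.r[nonzero[0]] + profile.dr / 2
        assert lo <= 2.07 <= hi

    def test_two_shell_peaks_recovered_within_one_bin(self):
        truth = sd.gen_site_trajectory(5)
        profile = hy.radial_distribution(truth.frames)
        report = hy.find_shells(profile)
        assert abs(report.peak1 - 2.5) <= profile.dr
        assert abs(report.peak2 - 3.2) <= profile.dr
        # equatorial shell closer than axial shell
        assert report.peak1 < report.peak2

    def test_translation_invariance_under_periodic_wrap(self):
        truth = sd.gen_site_trajectory(9, n_frames=20, n_bulk=50)
        base = hy.radial_distribution(truth.frames)
        shift = np.array([7.3, -4.1, 11.9])
        moved = [
            hy.Frame(
                coords=np.mod(f.coords + shift, f.box),
                elements=f.elements, roles=f.roles, box=f.box,
            )
            for f in truth.frames
        ]
        got = hy.radial_distribution(moved)
        np.testing.assert_allclose(got.g, base.g, rtol=1e-9, atol=1e-12)

    def test_matches_mdanalysis_interrdf(self):
        """Independent cross-check of the full g(r) against MDAnalysis's
        InterRDF on the same frames."""
        import MDAnalysis as mda
        from MDAnalysis.analysis.rdf import InterRDF

        truth = sd.gen_site_trajectory(12, n_frames=100, n_bulk=80)
        profile = hy.radial_distribution(truth.frames)

        n_atoms = len(truth.frames[0].coords)
        coords = np.stack([f.coords for f in truth.frames]).astype(np.float32)
        dims = np.tile(np.array([20.0, 20.0, 20.0, 90.0, 90.0, 90.0]),
                       (len(truth.frames), 1))
        u = mda.Universe.empty(n_atoms, trajectory=True)
        u.load_new(coords, dimensions=dims)
        ref = u.atoms[[0]]  # generator places the Cu first
        waters = u.atoms[1:]
        inter = InterRDF(ref, waters, nbins=len(profile.r), range=(0.0, 8.0))
        inter.run()
        np.testing.assert_allclose(profile.g, inter.results.rdf, rtol=2e-3, atol=5e-3)

    def test_rmax_beyond_half_box_rejected(self):
        truth = sd.gen_site_trajectory(2, n_frames=1, n_bulk=5)
        with pytest.raises(ValueError, match="half"):
            hy.radial_distribution(truth.frames, r_max=11.0)

    def test_reference_must_be_unique(self):
        f = _single_water_frames()[0]
        f.roles[1] = hy.ROLE_COPPER
        with pytest.raises(ValueError, match="exactly one"):
            hy.radial_distribution([f], rho=1.0)


class TestShellCoordination:
    def test_single_fixed_water_integrates_to_one(self):
        frames = _single_water_frames()
        rho = 1.0 / (4.0 / 3.0 * np.pi * 8.0**3)
        profile = hy.radial_distribution(frames, rho=rho)
        n = hy.shell_coordination(profile, (1.8, 2.4))
        assert n == pytest.approx(1.0, abs=0.02)

    def test_two_fixed_waters_integrate_to_two(self):
        frames = []
        for f1, f2 in zip(
            _single_water_frames(2.07, seed=1), _single_water_frames(2.34, seed=2)
        ):
            frames.append(hy.Frame(
                coords=np.vstack([f1.coords, f2.coords[1:]]),
                elements=np.array(["Cu", "O", "O"], dtype=object),
                roles=np.array([hy.ROLE_COPPER] + [hy.ROLE_WATER_O] * 2, dtype=object),
                box=None,
            ))
        rho = 2.0 / (4.0 / 3.0 * np.pi * 8.0**3)
        profile = hy.radial_distribution(frames, rho=rho)
        assert hy.shell_coordination(profile, (1.8, 2.6)) == pytest.approx(2.0, abs=0.04)

    def test_full_sphere_conserves_particle_count(self):
        truth = sd.gen_ideal_gas_frames(3, n_frames=300)
        profile = hy.radial_distribution(truth.frames)
        got = hy.shell_coordination(profile, (profile.r[0], profile.r[-1]))
        expected = 200 * (4.0 / 3.0 * np.pi * 8.0**3) / 20.0**3
        assert got == pytest.approx(expected, rel=0.02)

    def test_inverted_bounds_rejected(self):
        truth = sd.gen_ideal_gas_frames(4, n_frames=5)
        profile = hy.radial_distribution(truth.frames)
        with pytest.raises(ValueError, match="inverted"):
            hy.shell_coordination(profile, (5.0, 3.0))

    def test_matches_mdanalysis_interrdf_counts(self):
        """Cross-check: integrating this module's g(r) over the first
        shell agrees with direct per-frame distance counting."""
        truth = sd.gen_site_trajectory(6, n_frames=200)
        profile = hy.radial_distribution(truth.frames)
        report = hy.find_shells(profile)
        # direct count of waters inside min1, averaged over frames
        counts = []
        for f in truth.frames:
            cu = f.coords[f.select(hy.ROLE_COPPER)[0]]
            d = f.coords[f.select(hy.ROLE_WATER_O)] - cu
            d -= f.box * np.round(d / f.box)
            counts.append(np.sum(np.linalg.norm(d, axis=1) <= report.min1))
        assert report.coordination1 == pytest.approx(np.mean(counts), rel=0.1)


class TestFindShells:
    def test_two_gaussian_profile(self):
        r = np.arange(0.01, 8.0, 0.02)
        g = (
            2.0 * np.exp(-((r - 2.5) ** 2) / (2 * 0.1**2))
            + 1.5 * np.exp(-((r - 3.2) ** 2) / (2 * 0.1**2))
            + 1.0 * (r > 4.0)
        )
        profile = hy.RDFProfile(r=r, g=g, rho=0.0334, n_frames=1, dr=0.02)
        report = hy.find_shells(profile)
        assert abs(report.peak1 - 2.5) <= 0.02
        assert abs(report.peak2 - 3.2) <= 0.02
        assert report.peak1 < report.min1 < report.peak2 < report.min2

    def test_flat_profile_has_no_shells(self):
        r = np.arange(0.01, 8.0, 0.02)
        profile = hy.RDFProfile(r=r, g=np.ones_like(r), rho=0.0334, n_frames=1, dr=0.02)
        assert "no_shells" in hy.find_shells(profile).flags

    def test_single_peak_flagged(self):
        r = np.arange(0.01, 8.0, 0.02)
        g = 3.0 * np.exp(-((r - 2.1) ** 2) / (2 * 0.1**2))
        profile = hy.RDFProfile(r=r, g=g, rho=0.0334, n_frames=1, dr=0.02)
        report = hy.find_shells(profile)
        assert "first_shell_only" in report.flags
        assert report.peak2 is None


class TestSuperpose:
    def test_identical_sets(self, rng):
        x = rng.normal(size=(10, 3))
        assert hy.superpose(x, x).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self, rng):
        x = rng.normal(size=(10, 3))
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        y = x @ rot.T + np.array([5.0, -3.0, 2.0])
        res = hy.superpose(x, y)
        assert res.rmsd == pytest.approx(0.0, abs=1e-8)
        # recovered transform maps y back onto x
        back = y @ res.rotation.T + res.translation
        np.testing.assert_allclose(back, x, atol=1e-8)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=(10, 3))
            y = rng.normal(size=(10, 3))
            assert hy.superpose(x, y).rmsd == pytest.approx(
                quaternion_rmsd(x, y), abs=1e-8
            )

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(20):
            a, b, c = (rng.normal(size=(8, 3)) for _ in range(3))
            rab = hy.superpose(a, b).rmsd
            rba = hy.superpose(b, a).rmsd
            assert rab == pytest.approx(rba, abs=1e-9)
            rac = hy.superpose(a, c).rmsd
            rbc = hy.superpose(b, c).rmsd
            assert rac <= rab + rbc + 1e-9

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            hy.superpose(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


def _geometry_frames(coords_list):
    frames = []
    for coords in coords_list:
        n = len(coords)
        frames.append(hy.Frame(
            coords=np.asarray(coords, float),
            elements=np.array(["C"] * n, dtype=object),
            roles=np.array(["atom"] * n, dtype=object),
            box=None,
        ))
    return frames


class TestClusterFrames:
    def test_identical_frames_form_one_cluster(self, rng):
        base = rng.normal(size=(6, 3))
        assign = hy.cluster_frames(_geometry_frames([base] * 7))
        assert len(assign.centroids) == 1
        assert assign.members[0] == list(range(7))

    def test_two_separated_bundles(self, rng):
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(size=(6, 3)) * 8.0  # internally deformed, far in RMSD
        frames = _geometry_frames(
            [a + rng.normal(size=(6, 3)) * 0.05 for _ in range(4)]
            + [b + rng.normal(size=(6, 3)) * 0.05 for _ in range(3)]
        )
        assign = hy.cluster_frames(frames, cutoff=2.5)
        assert len(assign.centroids) == 2
        assert assign.members[0] == [0, 1, 2, 3]
        assert assign.members[1] == [4, 5, 6]

    def test_partition_property(self, rng):
        frames = _geometry_frames([rng.normal(size=(5, 3)) * 2 for _ in range(12)])
        assign = hy.cluster_frames(frames, cutoff=2.0)
        seen = sorted(i for members in assign.members for i in members)
        assert seen == list(range(12))
        for cid, members in enumerate(assign.members):
            assert assign.centroids[cid] in members
            assert all(assign.labels[i] == cid for i in members)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_oracle_on_small_sets(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        frames = _geometry_frames([rng.normal(size=(5, 3)) * 1.5 for _ in range(n)])
        assign = hy.cluster_frames(frames, cutoff=2.0)
        # oracle: independent RMSD (quaternion) and naive greedy loops
        dist = [
            [quaternion_rmsd(frames[i].coords, frames[j].coords) for j in range(n)]
            for i in range(n)
        ]
        expected = greedy_cluster(np.array(dist), 2.0)
        assert assign.members == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hy.cluster_frames([])
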