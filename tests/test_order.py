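"""Order parameter O(r), angle distributions, RDF, neighbor cutoff."""

import numpy as np
import pytest
from scipy.stats import kstest

from jaggr import (
    Box,
    Configuration,
    GeneratorSpec,
    MoleculeRecord,
    RdfProfile,
    Trajectory,
    angle_distribution,
    com_rdf,
    compute_axis_frame,
    first_neighbor_cutoff,
    generate_aligned,
    generate_pair,
    order_profile,
    p2,
)


def make_rod(molecule_id, com, axis, length=10.0, n=3):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    t = np.linspace(-0.5, 0.5, n)
    pos = np.asarray(com, float) + t[:, None] * length * axis
    return MoleculeRecord(molecule_id, pos, np.full(n, 12.0),
                          head_atom=0, tail_atom=n - 1)


def occupied_value(profile):
    k = np.flatnonzero(profile.pair_counts > 0)
    assert len(k) == 1
    return profile.o_values[k[0]]


class TestOrderProfile:
    @pytest.mark.parametrize("theta,expected", [
        (0.0, 1.0), (90.0, -0.5), (180.0, 1.0),
    ])
    def test_pair_anchor_values(self, box100, theta, expected):
        config = generate_pair(theta=theta, r=5.0, box=box100)
        prof = order_profile(Trajectory([config]), bin_width=0.5, r_max=10.0)
        assert occupied_value(prof) == pytest.approx(expected, abs=1e-12)

    def test_isotropic_bins_near_zero(self):
        spec = GeneratorSpec(n_molecules=1000, order_target=0.0,
                             box=(120, 120, 120), seed=21)
        prof = order_profile(generate_aligned(spec), bin_width=5.0, r_max=60.0)
        for k in np.flatnonzero(prof.pair_counts > 30):
            se = 1.0 / np.sqrt(prof.pair_counts[k])  # var(P2) <= 1 on [-0.5,1]
            assert abs(prof.o_values[k]) <= 3 * max(se, 0.05)

    def test_aligned_s08_bins_near_addition_theorem_value(self):
        """Pooled pairwise order for independent axes with S = 0.8 is
        S^2 = 0.64 (Legendre addition theorem); frames are i.i.d. redraws
        so pooling over frames drives the sampling error below 0.01."""
        spec = GeneratorSpec(n_molecules=2000, order_target=0.8,
                             box=(400, 400, 400), frames=8, seed=22)
        prof = order_profile(generate_aligned(spec), bin_width=10.0,
                             r_max=150.0)
        pooled = (np.nansum(prof.o_values * prof.pair_counts)
                  / prof.pair_counts.sum())
        assert pooled == pytest.approx(0.64, abs=0.01)

    def test_matches_double_loop_oracle(self):
        """Binned means equal a naive pair loop (minimum image, P2)."""
        from jaggr import minimum_image_distance, pair_angle
        spec = GeneratorSpec(n_molecules=40, order_target=0.4,
                             box=(60, 60, 60), seed=23)
        traj = generate_aligned(spec)
        bw, rmax = 2.0, 30.0
        prof = order_profile(traj, bin_width=bw, r_max=rmax)
        af = compute_axis_frame(traj[0])
        nbins = len(prof.bin_edges) - 1
        sums = np.zeros(nbins)
        counts = np.zeros(nbins, dtype=int)
        for i in range(af.n_molecules):
            for j in range(i + 1, af.n_molecules):
                d = minimum_image_distance(af.coms[i], af.coms[j], traj[0].box)
                if d >= rmax:
                    continue
                theta = pair_angle(af.axes[i], af.axes[j], oriented=True)
                k = min(int(d / bw), nbins - 1)
                sums[k] += p2(np.cos(np.radians(theta)))
                counts[k] += 1
        assert np.array_equal(prof.pair_counts, counts)
        for k in np.flatnonzero(counts):
            assert prof.o_values[k] == pytest.approx(sums[k] / counts[k],
                                                     abs=1e-12)
        for k in np.flatnonzero(counts == 0):
            assert np.isnan(prof.o_values[k])

    def test_values_within_bounds_and_rotation_invariant(self):
        from scipy.spatial.transform import Rotation
        spec = GeneratorSpec(n_molecules=60, order_target=0.5,
                             box=(80, 80, 80), seed=24)
        traj = generate_aligned(spec)
        prof = order_profile(traj, bin_width=2.0, r_max=40.0)
        pop = prof.pair_counts > 0
        assert np.all(prof.o_values[pop] >= -0.5 - 1e-12)
        assert np.all(prof.o_values[pop] <= 1.0 + 1e-12)
        # rotate every molecule about the box center: same profile
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        center = np.array([40.0, 40.0, 40.0])
        rotated = []
        for mol in traj[0].molecules:
            pos = (mol.positions - center) @ R.T + center
            rotated.append(MoleculeRecord(mol.molecule_id, pos, mol.masses,
                                          mol.head_atom, mol.tail_atom))
        traj_rot = Trajectory([Configuration(rotated, traj[0].box)])
        prof_rot = order_profile(traj_rot, bin_width=2.0, r_max=40.0)
        assert np.allclose(prof.o_values[pop], prof_rot.o_values[pop],
                           atol=1e-9)

    def test_pooled_equals_mean_of_frame_means_when_counts_equal(self, box100):
        frames = [generate_pair(theta=0.0, r=5.0, box=box100),
                  generate_pair(theta=90.0, r=5.0, box=box100)]
        traj = Trajectory(frames)
        pooled = order_profile(traj, bin_width=0.5, r_max=10.0,
                               averaging="pooled")
        per_frame = order_profile(traj, bin_width=0.5, r_max=10.0,
                                  averaging="per_frame")
        k = np.flatnonzero(pooled.pair_counts > 0)[0]
        assert pooled.o_values[k] == pytest.approx(0.25)  # (1 - 0.5) / 2
        assert per_frame.o_values[k] == pytest.approx(0.25)

    def test_input_validation(self, box100):
        with pytest.raises(ValueError, match="frames"):
            order_profile(Trajectory([]), r_max=10.0)
        config = generate_pair(theta=0.0, r=5.0, box=box100)
        with pytest.raises(ValueError, match="half"):
            order_profile(Trajectory([config]), r_max=80.0)


class TestAngleDistribution:
    def test_parallel_fixture_mass_in_first_bin(self):
        spec = GeneratorSpec(n_molecules=20, order_target=1.0,
                             box=(40, 40, 40), seed=31)
        dist = angle_distribution(generate_aligned(spec), r_max=10.0,
                                  bin_width=5.0)
        assert dist.density[0] * 5.0 == pytest.approx(1.0)
        assert np.allclose(dist.density[1:], 0.0)

    def test_isotropic_angles_follow_sine_law(self):
        """For independent uniform axes the inter-axis angle has density
        sin(theta)/2 on [0, 180] degrees (solid-angle law)."""
        spec = GeneratorSpec(n_molecules=400, order_target=0.0,
                             box=(50, 50, 50), seed=32)
        traj = generate_aligned(spec)
        # collect raw angles exactly as angle_distribution does
        from jaggr.order import _pair_arrays
        cos_all = []
        for frame in traj:
            dist, cosang, _ = _pair_arrays(frame)
            cos_all.append(cosang[dist <= 10.0])
        theta = np.degrees(np.arccos(np.concatenate(cos_all)))
        assert len(theta) > 100
        stat = kstest(theta, lambda t: 0.5 * (1 - np.cos(np.radians(t))))
        assert stat.pvalue > 0.01

    def test_density_integrates_to_one(self):
        spec = GeneratorSpec(n_molecules=100, order_target=0.3,
                             box=(50, 50, 50), seed=33)
        dist = angle_distribution(generate_aligned(spec), r_max=15.0,
                                  bin_width=5.0)
        width = np.diff(dist.bin_edges)
        assert (dist.density * width).sum() == pytest.approx(1.0, abs=1e-9)

    def test_parallel_antiparallel_mixture_concentrates_at_extremes(self):
        """A half parallel / half anti-parallel planted ensemble has >= 95%
        of its angle mass below 60 or above 120 degrees."""
        rng = np.random.default_rng(34)
        mols = []
        box = Box(60, 60, 60)
        for i in range(40):
            sign = 1.0 if i % 2 == 0 else -1.0
            # small angular jitter around +/- z
            jitter = rng.normal(scale=0.08, size=3)
            axis = np.array([0.0, 0.0, sign]) + jitter
            mols.append(make_rod(i, rng.uniform(10, 50, 3), axis))
        dist = angle_distribution(Trajectory([Configuration(mols, box)]),
                                  r_max=30.0, bin_width=5.0)
        centers = dist.bin_centers
        width = np.diff(dist.bin_edges)
        mass_extreme = (dist.density * width)[(centers < 60) | (centers > 120)].sum()
        assert mass_extreme >= 0.95

    def test_unoriented_axes_fold_with_warning(self, box100):
        mols = [MoleculeRecord(0, [[10, 10, 10], [20, 10, 10]], [1, 1]),
                MoleculeRecord(1, [[10, 15, 10], [10, 15, 20]], [1, 1])]
        traj = Trajectory([Configuration(mols, box100)])
        with pytest.warns(UserWarning, match="folded"):
            dist = angle_distribution(traj, r_max=20.0)
        assert dist.bin_edges[-1] == 90.0
        assert not dist.oriented

    def test_no_qualifying_pairs_raises(self, box100):
        config = generate_pair(theta=0.0, r=30.0, box=box100)
        with pytest.raises(ValueError, match="no molecule pairs"):
            angle_distribution(Trajectory([config]), r_max=10.0)


class TestComRdf:
    def test_uniform_gas_g_is_one(self):
        spec = GeneratorSpec(n_molecules=2000, order_target=0.0,
                             box=(100, 100, 100), seed=41)
        rdf = com_rdf(generate_aligned(spec), bin_width=0.5, r_max=40.0)
        sel = (rdf.bin_centers >= 3.0) & (rdf.bin_centers <= 40.0)
        g = rdf.g_values[sel]
        counts = rdf.counts[sel]
        se = np.sqrt(np.maximum(counts, 1)) / np.where(counts > 0, counts, 1) * g
        # bin-wise Poisson check plus a tight check on the mean
        assert np.all(np.abs(g - 1.0) <= 3 * np.maximum(se, 0.05))
        assert g.mean() == pytest.approx(1.0, abs=0.01)

    def test_two_molecules_closed_form_normalization(self, box100):
        config = generate_pair(theta=0.0, r=8.1, box=box100)
        rdf = com_rdf(Trajectory([config]), bin_width=1.0, r_max=40.0)
        k = np.flatnonzero(rdf.counts)[0]
        assert rdf.bin_edges[k] <= 8.1 < rdf.bin_edges[k + 1]
        shell = 4.0 / 3.0 * np.pi * (rdf.bin_edges[k + 1] ** 3
                                     - rdf.bin_edges[k] ** 3)
        expected = 1.0 / (1.0 * shell / 100.0 ** 3)  # N(N-1)/2 = 1
        assert rdf.g_values[k] == pytest.approx(expected, rel=1e-12)

    def test_planted_first_shell_peaks_below_10(self):
        """Pairs planted ~8 A apart put the first RDF peak within 10 A."""
        rng = np.random.default_rng(42)
        box = Box(200, 200, 200)
        frames = []
        spec = GeneratorSpec(n_molecules=30,
                             planted_clusters=((2, 8.5),) * 15,
                             box=(200, 200, 200), seed=43)
        from jaggr import generate_clustered
        traj, _ = generate_clustered(spec, cutoff=17.0)
        rdf = com_rdf(traj, bin_width=1.0, r_max=30.0)
        peak_r = rdf.bin_centers[np.argmax(rdf.g_values)]
        assert peak_r < 10.0


class TestFirstNeighborCutoff:
    def make_rdf(self, g):
        g = np.asarray(g, float)
        edges = np.arange(len(g) + 1, dtype=float)
        return RdfProfile(bin_edges=edges, g_values=g,
                          counts=(g > 0).astype(int), n_molecules=10,
                          box_volume=1e6, frames_used=1)

    def test_single_shell_with_empty_tail(self):
        # peak at r ~ 8, empty beyond 12
        g = [0, 0, 0, 0, 0, 0, 1, 3, 6, 4, 2, 1, 0, 0, 0, 0]
        cutoff = first_neighbor_cutoff(self.make_rdf(g))
        assert 8.0 <= cutoff <= 12.0

    def test_two_shells_minimum_between(self):
        # shells at ~8 and ~15
        g = [0, 0, 0, 0, 0, 0, 1, 3, 6, 4, 2, 1, 2, 4, 5, 3, 1, 0]
        cutoff = first_neighbor_cutoff(self.make_rdf(g))
        assert 8.0 < cutoff < 15.0

    def test_flat_profile_errors(self):
        with pytest.raises(ValueError, match="peak"):
            first_neighbor_cutoff(self.make_rdf(np.ones(20)))
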