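import numpy as np
import pytest

from conftest import random_rotation

from hicnb import (
    AlignmentOptions,
    ContactMatrix,
    InputError,
    Structure3D,
    coarsen_structure,
    distance_spearman,
    downsample_counts,
    filter_common_beads,
    generate_structure,
    rescale_structure,
    rmsd,
)


@pytest.fixture()
def walk30():
    return generate_structure(30, "random_walk", seed=4)


class TestRMSD:
    def test_identity_is_zero(self, walk30):
        assert rmsd(walk30, walk30) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, walk30):
        rng = np.random.default_rng(1)
        moved = Structure3D(walk30.coords @ random_rotation(rng).T + rng.standard_normal(3))
        assert rmsd(walk30, moved) == pytest.approx(0.0, abs=1e-8)

    def test_mirror_image_reflection_semantics(self, walk30):
        mirrored = Structure3D(walk30.coords * np.array([-1.0, 1.0, 1.0]))
        assert rmsd(walk30, mirrored, AlignmentOptions(allow_reflection=True)) == pytest.approx(
            0.0, abs=1e-8
        )
        strict = rmsd(walk30, mirrored, AlignmentOptions(allow_reflection=False))
        assert strict > 0

        # brute-force oracle: best RMSD over many random proper rotations
        from scipy.spatial.transform import Rotation

        a = walk30.coords - walk30.coords.mean(axis=0)
        b = mirrored.coords - mirrored.coords.mean(axis=0)
        rots = Rotation.random(4000, random_state=0).as_matrix()
        vals = np.sqrt(((a @ rots.transpose(0, 2, 1) - b) ** 2).sum(axis=2).mean(axis=1))
        oracle = vals.min()
        assert strict <= oracle + 1e-9  # ours is the optimum
        assert strict == pytest.approx(oracle, rel=0.05)

    def test_symmetric_without_scaling(self, walk30):
        rng = np.random.default_rng(2)
        other = Structure3D(walk30.coords + 0.3 * rng.standard_normal((30, 3)))
        assert rmsd(walk30, other) == pytest.approx(rmsd(other, walk30), abs=1e-10)

    def test_scaled_copy_recovered_with_scaling(self, walk30):
        scaled = Structure3D(2.5 * walk30.coords)
        assert rmsd(walk30, scaled, AlignmentOptions(allow_scaling=True)) == pytest.approx(
            0.0, abs=1e-8
        )
        assert rmsd(walk30, scaled) > 0  # rigid alone cannot absorb scale

    def test_too_few_common_beads_rejected(self, walk30):
        sparse = walk30.copy()
        sparse.valid_mask[:] = False
        sparse.valid_mask[:2] = True
        with pytest.raises(InputError):
            rmsd(walk30, sparse)


class TestDistanceSpearman:
    def test_self_correlation_is_one(self, walk30):
        assert distance_spearman(walk30, walk30) == pytest.approx(1.0)

    def test_isotropic_scaling_preserves_ranks(self):
        # tie-free point cloud: a unit-step walk has exactly tied adjacent
        # distances whose ranks rounding would reorder after scaling
        rng = np.random.default_rng(8)
        a = Structure3D(rng.standard_normal((30, 3)))
        scaled = Structure3D(7.0 * a.coords)
        assert distance_spearman(a, scaled) == pytest.approx(1.0)

    def test_independent_clouds_nearly_uncorrelated(self):
        """Empirical null: unrelated geometries share no distance ranking.

        Independent Gaussian clouds are the right null here; independent
        random *walks* still correlate (~0.6) through the common polymer
        backbone, since distance grows with |i-j| in both.
        """
        rhos = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = Structure3D(rng.standard_normal((100, 3)))
            b = Structure3D(np.random.default_rng(1000 + seed).standard_normal((100, 3)))
            rhos.append(abs(distance_spearman(a, b)))
        assert np.median(rhos) < 0.3

    def test_backbone_correlation_between_independent_walks(self):
        # shared chain structure correlates distances well below identity
        rhos = [
            distance_spearman(
                generate_structure(100, "random_walk", seed=s),
                generate_structure(100, "random_walk", seed=1000 + s),
            )
            for s in range(5)
        ]
        assert 0.2 < np.median(rhos) < 0.9

    def test_constant_distances_rejected(self):
        # regular tetrahedron: all six distances are the same float exactly
        tetra = Structure3D(
            np.array([[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]])
        )
        with pytest.raises(InputError):
            distance_spearman(tetra, tetra)


class TestRescale:
    def test_all_beads_fit_nucleus(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((40, 3))
        out = rescale_structure(Structure3D(x), diameter=100.0, quantile=1.0)
        radii = np.linalg.norm(out.coords, axis=1)
        assert radii.max() == pytest.approx(50.0, rel=1e-12)

    def test_idempotent_up_to_centering(self):
        rng = np.random.default_rng(1)
        s = Structure3D(rng.standard_normal((25, 3)) + 5.0)
        once = rescale_structure(s, 10.0, 0.9)
        twice = rescale_structure(once, 10.0, 0.9)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-10)

    def test_quantile_leaves_outlier_outside(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((100, 3))
        x[0] = [40.0, 0.0, 0.0]
        out = rescale_structure(Structure3D(x), diameter=100.0, quantile=0.99)
        radii = np.linalg.norm(out.coords - out.coords.mean(axis=0), axis=1)
        assert radii[0] > 50.0
        assert np.quantile(np.linalg.norm(out.coords, axis=1), 0.99) == pytest.approx(50.0)


class TestCoarsen:
    def test_factor_one_is_identity(self, walk30):
        np.testing.assert_array_equal(coarsen_structure(walk30, 1).coords, walk30.coords)

    def test_pair_average(self):
        s = Structure3D(np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        out = coarsen_structure(s, 2)
        assert out.n == 1
        np.testing.assert_allclose(out.coords[0], [1.0, 0, 0])

    def test_invalid_member_ignored_in_group_mean(self):
        s = Structure3D(np.array([[1.0, 1, 1], [np.nan] * 3, [5.0, 5, 5], [7.0, 7, 7]]))
        out = coarsen_structure(s, 2)
        np.testing.assert_allclose(out.coords[0], [1.0, 1, 1])
        np.testing.assert_allclose(out.coords[1], [6.0, 6, 6])

    def test_all_invalid_group_is_invalid(self):
        s = Structure3D(np.array([[np.nan] * 3, [np.nan] * 3, [1.0, 0, 0], [3.0, 0, 0]]))
        out = coarsen_structure(s, 2)
        assert not out.valid_mask[0] and out.valid_mask[1]

    def test_commutes_with_rigid_motion(self, walk30):
        rng = np.random.default_rng(5)
        rot, t = random_rotation(rng), rng.standard_normal(3)
        moved = Structure3D(walk30.coords @ rot.T + t)
        a = coarsen_structure(moved, 3).coords
        b = coarsen_structure(walk30, 3).coords @ rot.T + t
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_groups_anchor_at_chromosome_starts(self):
        coords = np.arange(15.0).reshape(5, 3)
        s = Structure3D(
            coords,
            chrom=np.array(["a", "a", "a", "b", "b"], object),
            bin_index=np.array([0, 1, 2, 0, 1]),
        )
        out = coarsen_structure(s, 2)
        assert list(out.chrom) == ["a", "a", "b"]
        np.testing.assert_allclose(out.coords[1], coords[2])  # trailing partial group


class TestDownsample:
    def make(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        c = rng.integers(0, 60, size=(n, n))
        c = np.triu(c, 1)
        return ContactMatrix(c + c.T)

    def test_fraction_one_identity(self):
        m = self.make()
        np.testing.assert_array_equal(downsample_counts(m, 1.0, 0).counts, m.counts)

    def test_fraction_zero_empties(self):
        assert downsample_counts(self.make(), 0.0, 0).counts.sum() == 0

    def test_half_total_binomial_concentration(self):
        m = self.make(3)
        total = m.counts.sum() // 2  # upper triangle
        out_total = downsample_counts(m, 0.5, 7).counts.sum() // 2
        assert abs(out_total - 0.5 * total) <= 3 * np.sqrt(total * 0.25)

    def test_composition_matches_single_thinning(self):
        """Thinning by f1 then f2 is distributed as thinning by f1*f2."""
        m = self.make(5, n=8)
        t_two, t_one = [], []
        for seed in range(200):
            two = downsample_counts(downsample_counts(m, 0.6, seed), 0.5, 10_000 + seed)
            one = downsample_counts(m, 0.3, 20_000 + seed)
            t_two.append(two.counts.sum())
            t_one.append(one.counts.sum())
        t_two, t_one = np.array(t_two, float), np.array(t_one, float)
        se = np.hypot(t_two.std() / np.sqrt(200), t_one.std() / np.sqrt(200))
        assert abs(t_two.mean() - t_one.mean()) < 4 * se + 1e-9
        assert t_two.var() == pytest.approx(t_one.var(), rel=0.5)

    def test_bad_fraction_rejected(self):
        with pytest.raises(InputError):
            downsample_counts(self.make(), 1.5, 0)


class TestFilterCommonBeads:
    def test_zero_row_in_either_matrix_invalidates_both(self):
        rng = np.random.default_rng(0)
        s1 = generate_structure(6, "random_walk", seed=1)
        s2 = generate_structure(6, "random_walk", seed=2)
        c = rng.integers(1, 9, size=(6, 6))
        c = np.triu(c, 1)
        ma = ContactMatrix(c + c.T)
        cb = (c + c.T).copy()
        cb[4, :] = cb[:, 4] = 0
        mb = ContactMatrix(cb)
        fa, fb = filter_common_beads(s1, s2, ma, mb)
        assert not fa.valid_mask[4] and not fb.valid_mask[4]
        assert fa.valid_mask.sum() == 5

    def test_identity_when_no_zero_marginals(self):
        rng = np.random.default_rng(1)
        s1 = generate_structure(5, "random_walk", seed=3)
        s2 = generate_structure(5, "random_walk", seed=4)
        c = rng.integers(1, 9, size=(5, 5))
        c = np.triu(c, 1)
        m = ContactMatrix(c + c.T)
        fa, fb = filter_common_beads(s1, s2, m, m)
        assert fa.valid_mask.all() and fb.valid_mask.all()

    def test_everything_filtered_is_error(self):
        s1 = generate_structure(4, "random_walk", seed=5)
        s2 = generate_structure(4, "random_walk", seed=6)
        ma = ContactMatrix(np.zeros((4, 4)))
        mb = ContactMatrix(np.ones((4, 4)) - np.eye(4))
        with pytest.raises(InputError):
            filter_common_beads(s1, s2, ma, mb)
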