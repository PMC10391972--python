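import numpy as np
import pytest

from isomigrate import (
    SimilarityMatrix,
    hclust_cut,
    population_cluster_proportions,
    schoeners_d,
    similarity_matrix,
    spatial_kmeans,
    zonal_max_membership,
)
from isomigrate.clustering import ClusterMap
from isomigrate.raster import RasterGrid
from conftest import make_surface


def _random_surfaces(rng, n, shape=(6, 6), centers=None):
    """Surfaces with unimodal Gaussian-ish bumps, optionally around centers."""
    out = []
    rows, cols = np.indices(shape)
    for i in range(n):
        if centers is None:
            rc, cc = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        else:
            rc, cc = centers[i % len(centers)]
            rc, cc = rc + rng.normal(0, 0.5), cc + rng.normal(0, 0.5)
        p = np.exp(-((rows - rc) ** 2 + (cols - cc) ** 2) / 4.0)
        p /= p.sum()
        out.append(make_surface(p, individual_id=f"s{i}"))
    return out


class TestSchoenersD:
    def test_identity_is_one(self):
        s = make_surface([[0.4, 0.6]])
        assert schoeners_d(s, s) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        a = make_surface([[1.0, 0.0]])
        b = make_surface([[0.0, 1.0]])
        assert schoeners_d(a, b) == pytest.approx(0.0)

    def test_two_cell_hand_value(self):
        a = make_surface([[0.5, 0.5]])
        b = make_surface([[1.0, 0.0]])
        assert schoeners_d(a, b) == pytest.approx(0.5)

    def test_symmetric_and_bounded(self, rng):
        surfs = _random_surfaces(rng, 6)
        for a in surfs:
            for b in surfs:
                d1, d2 = schoeners_d(a, b), schoeners_d(b, a)
                assert d1 == pytest.approx(d2)
                assert 0.0 <= d1 <= 1.0
        assert schoeners_d(surfs[0], surfs[0]) == pytest.approx(1.0)


class TestSimilarityMatrix:
    def test_identical_surfaces_give_ones_and_zero_sd(self):
        s = make_surface([[0.3, 0.7]])
        t = make_surface([[0.3, 0.7]], individual_id="y")
        sim = similarity_matrix([s, t], n_boot=20, seed=0)
        assert np.allclose(sim.values, 1.0)
        assert np.allclose(sim.boot_sd, 0.0)

    def test_deterministic_under_seed(self, rng):
        surfs = _random_surfaces(rng, 4)
        a = similarity_matrix(surfs, n_boot=5, seed=42)
        b = similarity_matrix(surfs, n_boot=5, seed=42)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.boot_sd, b.boot_sd)

    def test_point_estimates_match_pairwise_calls(self, rng):
        surfs = _random_surfaces(rng, 3)
        sim = similarity_matrix(surfs, n_boot=1, seed=0)
        for i in range(3):
            for j in range(3):
                assert sim.values[i, j] == pytest.approx(
                    schoeners_d(surfs[i], surfs[j]), abs=1e-12
                )

    def test_invalid_boot_count(self, rng):
        with pytest.raises(ValueError):
            similarity_matrix(_random_surfaces(rng, 2), n_boot=0)


class TestHclustCut:
    def _block_matrix(self):
        # two perfect blocks: within-block D = 1, between-block D = 0.1
        ids = ["a1", "a2", "a3", "b1", "b2"]
        v = np.full((5, 5), 0.1)
        v[:3, :3] = 1.0
        v[3:, 3:] = 1.0
        return SimilarityMatrix(ids=ids, values=v)

    def test_two_blocks_recovered(self):
        labels = hclust_cut(self._block_matrix())
        assert labels["a1"] == labels["a2"] == labels["a3"]
        assert labels["b1"] == labels["b2"]
        assert labels["a1"] != labels["b1"]

    def test_high_cut_gives_one_cluster(self):
        labels = hclust_cut(self._block_matrix(), cut_height=3.0)
        assert set(labels.values()) == {1}

    def test_low_cut_gives_singletons(self, rng):
        surfs = _random_surfaces(rng, 4)
        sim = similarity_matrix(surfs, n_boot=1, seed=0)
        labels = hclust_cut(sim, cut_height=1e-12)
        assert len(set(labels.values())) == 4

    def test_partition_invariant_to_input_order(self):
        sim = self._block_matrix()
        perm = [3, 0, 4, 1, 2]
        permuted = SimilarityMatrix(
            ids=[sim.ids[i] for i in perm],
            values=sim.values[np.ix_(perm, perm)],
        )
        base = hclust_cut(sim)
        shuffled = hclust_cut(permuted)
        # same partition up to relabeling
        for x in sim.ids:
            for y in sim.ids:
                assert (base[x] == base[y]) == (shuffled[x] == shuffled[y])

    def test_constant_profiles_fall_back_to_max_distance(self):
        ids = ["a", "b", "c"]
        v = np.ones((3, 3))  # zero-variance rows: correlation undefined
        labels = hclust_cut(SimilarityMatrix(ids=ids, values=v), cut_height=0.5)
        assert len(set(labels.values())) == 3


class TestSpatialKmeans:
    def test_k1_covers_all_valid_cells(self, rng):
        surfs = _random_surfaces(rng, 3)
        cmap = spatial_kmeans(surfs, k=1, seed=0)
        labels = cmap.labels.values[cmap.labels.mask]
        assert set(labels) == {1.0}

    def test_two_blobs_split_spatially(self, rng):
        surfs = _random_surfaces(rng, 10, shape=(12, 12), centers=[(3, 3), (9, 9)])
        cmap = spatial_kmeans(surfs, k=2, geo_weight=100, seed=0)
        lab = cmap.labels.values
        assert lab[3, 3] != lab[9, 9]

    def test_deterministic_under_seed(self, rng):
        surfs = _random_surfaces(rng, 5)
        a = spatial_kmeans(surfs, k=3, seed=7)
        b = spatial_kmeans(surfs, k=3, seed=7)
        assert np.array_equal(a.labels.values, b.labels.values)

    def test_k_exceeding_cells_errors(self, rng):
        surfs = _random_surfaces(rng, 2, shape=(2, 2))
        with pytest.raises(ValueError):
            spatial_kmeans(surfs, k=5)

    def test_geo_weight_bounds(self, rng):
        surfs = _random_surfaces(rng, 2)
        with pytest.raises(ValueError):
            spatial_kmeans(surfs, k=2, geo_weight=0.5)

    def test_contiguity_never_drops_with_geo_weight(self, rng):
        """Higher geographic weighting yields equal or more contiguous maps
        on a seeded scenario of spatially unstructured surfaces."""
        surfs = []
        for i in range(8):
            p = rng.random((10, 10)) ** 3
            p /= p.sum()
            surfs.append(make_surface(p, individual_id=f"n{i}"))

        def contiguity(cmap):
            lab = cmap.labels.values
            same = (lab[:-1, :] == lab[1:, :]).sum() + (lab[:, :-1] == lab[:, 1:]).sum()
            total = lab[:-1, :].size + lab[:, :-1].size
            return same / total

        scores = [contiguity(spatial_kmeans(surfs, k=2, geo_weight=w, seed=3))
                  for w in (1, 10, 30, 50, 100)]
        assert all(a <= b + 1e-9 for a, b in zip(scores, scores[1:]))


class TestZonalMembership:
    def _two_zone_map(self):
        labels = np.ones((2, 4))
        labels[:, 2:] = 2.0
        grid = RasterGrid(values=labels, mask=np.ones((2, 4), bool))
        return ClusterMap(labels=grid, k=2)

    def test_mass_in_second_zone(self):
        surf = make_surface([[0.0, 0.0, 0.1, 0.6], [0.0, 0.0, 0.1, 0.2]])
        df = zonal_max_membership([surf], self._two_zone_map())
        assert df.loc[0, "cluster"] == 2
        assert df.loc[0, "max_c2"] == pytest.approx(0.6)

    def test_uniform_tie_goes_to_lowest_cluster(self):
        surf = make_surface([[0.125] * 4, [0.125] * 4])
        df = zonal_max_membership([surf], self._two_zone_map())
        assert df.loc[0, "cluster"] == 1

    def test_proportions_match_hand_tally(self):
        cmap = self._two_zone_map()
        surfaces = [
            make_surface([[0.7, 0.1, 0.1, 0.1], [0.0, 0.0, 0.0, 0.0]], "p1_a"),
            make_surface([[0.6, 0.2, 0.1, 0.1], [0.0, 0.0, 0.0, 0.0]], "p1_b"),
            make_surface([[0.1, 0.1, 0.7, 0.1], [0.0, 0.0, 0.0, 0.0]], "p1_c"),
            make_surface([[0.1, 0.1, 0.1, 0.7], [0.0, 0.0, 0.0, 0.0]], "p2_a"),
        ]
        df = zonal_max_membership(surfaces, cmap)
        props = population_cluster_proportions(
            {"p1_a": "P1", "p1_b": "P1", "p1_c": "P1", "p2_a": "P2"}, df
        )
        assert props.loc["P1", 1] == pytest.approx(2 / 3)
        assert props.loc["P1", 2] == pytest.approx(1 / 3)
        assert props.loc["P2", 2] == pytest.approx(1.0)
        assert np.allclose(props.sum(axis=1), 1.0)

    def test_unmapped_id_errors(self):
        surf = make_surface([[0.5, 0.5, 0.0, 0.0], [0.0, 0.0, 0.0, 0.0]], "zz")
        df = zonal_max_membership([surf], self._two_zone_map())
        with pytest.raises(ValueError, match="zz"):
            population_cluster_proportions({}, df)
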