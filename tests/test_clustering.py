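import numpy as np
import pytest

from lingsync import (
    DegeneracyError,
    ProfileMatrix,
    brute_force_kmeans,
    choose_elbow,
    cluster_centers_table,
    elbow_scan,
    kmeans_fit,
    load_fixture_dyad,
    pca_project,
    zscore,
)
from lingsync.clustering import _partitions_into_k

from conftest import blob_matrix


def random_matrix(n_rows, seed, dyad="R"):
    rng = np.random.default_rng(seed)
    labels = tuple(("client", i + 1) for i in range(n_rows))
    return ProfileMatrix(dyad, labels, rng.normal(0, 1, (n_rows, 4)))


class TestKmeansFit:
    def test_k_equals_rows_zero_distortion(self):
        m = random_matrix(6, seed=0)
        sol = kmeans_fit(m, k=6)
        assert sol.distortion == pytest.approx(0.0, abs=1e-12)

    def test_k1_closed_form(self):
        m = random_matrix(8, seed=1)
        sol = kmeans_fit(m, k=1)
        assert np.allclose(sol.centers[0], m.values.mean(axis=0))
        tss = ((m.values - m.values.mean(axis=0)) ** 2).sum()
        assert sol.distortion == pytest.approx(tss)

    def test_k_out_of_range(self):
        m = random_matrix(4, seed=2)
        for k in (0, 5):
            with pytest.raises(ValueError):
                kmeans_fit(m, k=k)

    def test_deterministic_given_seed(self):
        m = random_matrix(12, seed=3)
        s1 = kmeans_fit(m, k=3, seed=11)
        s2 = kmeans_fit(m, k=3, seed=11)
        assert s1.assignments == s2.assignments
        assert np.array_equal(s1.centers, s2.centers)
        assert s1.distortion == s2.distortion

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_bruteforce_on_toy_instances(self, seed, k):
        m = random_matrix(6, seed=seed)
        sol = kmeans_fit(m, k=k, n_restarts=50)
        _, opt = brute_force_kmeans(m, k)
        # restarted Lloyd can never beat the global optimum
        assert sol.distortion >= opt - 1e-9
        assert sol.distortion == pytest.approx(opt, rel=1e-9, abs=1e-9)


class TestBruteForce:
    def test_partition_count(self):
        # Stirling numbers S(4,2)=7, S(5,3)=25
        assert sum(1 for _ in _partitions_into_k(4, 2)) == 7
        assert sum(1 for _ in _partitions_into_k(5, 3)) == 25

    def test_identical_points_k1(self):
        m = ProfileMatrix(
            "D", (("client", 1), ("client", 2)), np.ones((2, 4))
        )
        _, ss = brute_force_kmeans(m, 1)
        assert ss == pytest.approx(0.0)

    def test_square_corners_hand_geometry(self):
        # 4 corners of a unit square: best 2-partition pairs adjacent
        # corners; each pair has SS = 2 * (1/2)^2 = 0.5, total 1.0
        corners = np.array(
            [[0, 0, 0, 0], [0, 1, 0, 0], [1, 0, 0, 0], [1, 1, 0, 0]], float
        )
        m = ProfileMatrix(
            "D", tuple(("client", i + 1) for i in range(4)), corners
        )
        assignments, ss = brute_force_kmeans(m, 2)
        assert ss == pytest.approx(1.0)
        groups = {}
        for lab, c in assignments.items():
            groups.setdefault(c, []).append(lab[1])
        # paired corners are adjacent (distance 1), never opposite
        for members in groups.values():
            pts = corners[[i - 1 for i in members]]
            assert np.sum((pts[0] - pts[1]) ** 2) == pytest.approx(1.0)

    def test_size_cap(self):
        with pytest.raises(ValueError):
            brute_force_kmeans(random_matrix(11, 0), 2)
        with pytest.raises(ValueError):
            brute_force_kmeans(random_matrix(5, 0), 4)


class TestElbow:
    def test_three_separated_blobs_chosen_3(self):
        centers = np.array(
            [[0, 0, 0, 0], [20, 0, 0, 0], [0, 20, 0, 0]], float
        )
        m = blob_matrix(centers, rows_per_blob=8, noise_sd=0.5, seed=4)
        scan = elbow_scan(m, n_restarts=10)
        assert scan.chosen_k == 3 and not scan.flat

    def test_distortion_non_increasing(self):
        m = random_matrix(20, seed=5)
        scan = elbow_scan(m, n_restarts=10)
        assert all(
            a >= b - 1e-9 for a, b in zip(scan.distortions, scan.distortions[1:])
        )

    def test_kmax_capped_at_rows_minus_1(self):
        m = random_matrix(6, seed=6)
        scan = elbow_scan(m, n_restarts=5)
        assert max(scan.k_values) == 5

    def test_linear_decay_is_flat_and_falls_back(self):
        # exactly linear distortion decay has zero curvature everywhere:
        # no elbow exists, the smallest interior k is returned, flagged flat
        chosen, flat = choose_elbow([1, 2, 3, 4, 5], [100, 80, 60, 40, 20])
        assert chosen == 2 and flat

    def test_clear_elbow_not_flat(self):
        chosen, flat = choose_elbow([1, 2, 3, 4, 5], [100, 20, 15, 12, 10])
        assert chosen == 2 and not flat

    def test_choose_elbow_tie_breaks_smallest_k(self):
        # equal curvature at k=2 and k=3
        chosen, _ = choose_elbow([1, 2, 3, 4], [10, 4, 1, 0.5])
        assert chosen == 2

    def test_fixture_dyads_elbow(self):
        for dyad, expected_k in (("B", 2), ("C", 2)):
            scan = elbow_scan(zscore(load_fixture_dyad(dyad)), n_restarts=20)
            assert scan.chosen_k == expected_k


class TestCenters:
    def test_recomputed_means_match_solution_centers(self):
        m = zscore(load_fixture_dyad("B"))
        sol = kmeans_fit(m, 2)
        centers, separations = cluster_centers_table(sol, m)
        assert np.allclose(centers.to_numpy(), sol.centers, atol=1e-9)
        assert separations.shape == (2, 2)
        assert separations.iloc[0, 1] > 0

    def test_k1_center_is_origin_for_standardized(self):
        m = zscore(random_matrix(10, seed=8))
        sol = kmeans_fit(m, 1)
        centers, _ = cluster_centers_table(sol, m)
        assert np.allclose(centers.to_numpy(), 0, atol=1e-9)

    def test_cbt_dyad_centers_split_on_clout(self):
        # the two clusters separate therapist (high clout) from client (low)
        m = zscore(load_fixture_dyad("B"))
        sol = kmeans_fit(m, 2)
        centers, _ = cluster_centers_table(sol, m)
        clout = centers["clout"].to_numpy()
        assert clout.min() < 0 < clout.max()
        t_cluster = sol.cluster_of("therapist", 1)
        assert clout[t_cluster] > 0


class TestPca:
    def test_planar_data_fully_explained(self):
        rng = np.random.default_rng(9)
        basis = rng.normal(0, 1, (2, 4))
        coords2d = rng.normal(0, 1, (12, 2))
        m = ProfileMatrix(
            "D",
            tuple(("client", i + 1) for i in range(12)),
            coords2d @ basis,
        )
        proj = pca_project(m)
        assert sum(proj.explained_variance_fractions) == pytest.approx(1.0, abs=1e-9)

    def test_rank_deficient_rejected(self):
        m = ProfileMatrix(
            "D",
            tuple(("client", i + 1) for i in range(4)),
            np.outer([1, 2, 3, 4.0], [1, 1, 1, 1]),
        )
        with pytest.raises(DegeneracyError):
            pca_project(m)

    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            pca_project(random_matrix(2, seed=0))

    def test_beats_random_rank2_projections(self):
        # PCA keeps at least as much pairwise squared distance as any
        # random orthonormal rank-2 projection
        m = random_matrix(15, seed=10)
        proj = pca_project(m)

        def sq_dist_sum(coords):
            diff = coords[:, None, :] - coords[None, :, :]
            return (diff**2).sum()

        pca_sum = sq_dist_sum(proj.coordinates)
        rng = np.random.default_rng(11)
        centered = m.values - m.values.mean(axis=0)
        for _ in range(20):
            q, _r = np.linalg.qr(rng.normal(0, 1, (4, 2)))
            assert pca_sum >= sq_dist_sum(centered @ q) - 1e-9

    def test_cbt_dyad_polarized_in_2d(self):
        # therapist and client rows are linearly separable in the projection
        m = zscore(load_fixture_dyad("B"))
        proj = pca_project(m)
        from sklearn.svm import LinearSVC

        y = [r == "therapist" for r, _ in proj.labels]
        clf = LinearSVC(C=1e6).fit(proj.coordinates, y)
        assert clf.score(proj.coordinates, y) == 1.0
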