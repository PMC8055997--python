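"""Cluster-number selection: PAM/silhouette, gap statistic, GMM-BIC, consensus."""

import itertools

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from sklearn.metrics import adjusted_rand_score

from snpdelim.cluster import (
    ClusterAssignment,
    GapStatisticKMeans,
    GaussianMixtureBIC,
    PAMSilhouette,
    average_silhouette,
    consensus,
    gaussian_bic,
    haplotypes_to_samples,
    pam,
    within_dispersion,
)
from snpdelim.vae import LatentEmbedding


def silhouette_from_definition(X, labels):
    """s(i) = (b - a) / max(a, b), averaged; independent of sklearn."""
    n = len(X)
    D = cdist(X, X)
    vals = []
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        a = D[i, same].mean()
        b = min(D[i, labels == c].mean() for c in np.unique(labels) if c != labels[i])
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def blobs(rng, centers, n_per, std):
    pts, lab = [], []
    for c, ctr in enumerate(centers):
        pts.append(rng.normal(ctr, std, size=(n_per, len(ctr))))
        lab += [c] * n_per
    return np.vstack(pts), np.array(lab)


class TestPAM:
    def test_two_separated_blobs_select_two(self):
        rng = np.random.default_rng(0)
        X, _ = blobs(rng, [(0, 0), (5, 0)], 10, 0.05)
        est = PAMSilhouette(k_min=2, k_max=6).fit(X)
        assert est.k_ == 2

    def test_average_silhouette_matches_hand_arithmetic(self):
        X = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], dtype=float)
        labels, _ = pam(X, 2)
        impl = average_silhouette(X, labels)
        # by hand: a = 1, b = mean(10, sqrt(101)) for every point
        b = (10 + np.sqrt(101)) / 2
        hand = (b - 1) / b
        assert impl == pytest.approx(hand, abs=1e-12)
        assert impl == pytest.approx(silhouette_from_definition(X, labels), abs=1e-12)

    def test_silhouette_equals_definition_on_random_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        labels, _ = pam(X, 3)
        assert average_silhouette(X, labels) == pytest.approx(
            silhouette_from_definition(X, labels), abs=1e-12
        )

    def test_pam_minimises_total_distance_on_small_inputs(self):
        # exhaustive medoid search agrees with build+swap on <= 8 points
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 2))
        D = cdist(X, X)
        best = min(
            D[:, list(m)].min(axis=1).sum()
            for m in itertools.combinations(range(8), 2)
        )
        labels, med = pam(X, 2)
        assert D[:, med].min(axis=1).sum() == pytest.approx(best)

    def test_identical_points_reported_as_degenerate(self):
        with pytest.raises(ValueError, match="identical"):
            PAMSilhouette().fit(np.ones((5, 2)))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            PAMSilhouette().fit(np.zeros((2, 2)))


class TestGapStatistic:
    def test_single_blob_selects_one(self):
        hits = 0
        for seed in range(10):
            X = np.random.default_rng(seed).normal(size=(40, 2))
            est = GapStatisticKMeans(k_min=1, k_max=5, B=30, random_state=seed).fit(X)
            hits += est.k_ == 1
        assert hits >= 8

    def test_four_blobs_selected(self):
        rng = np.random.default_rng(3)
        X, _ = blobs(rng, [(0, 0), (6, 0), (0, 6), (6, 6)], 12, 0.3)
        est = GapStatisticKMeans(k_min=1, k_max=8, B=50, random_state=0).fit(X)
        assert est.k_ == 4

    def test_log_dispersion_strictly_decreases(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 2))
        est = GapStatisticKMeans(k_min=1, k_max=6, B=10, random_state=0).fit(X)
        w = [est.log_w_[k] for k in sorted(est.log_w_)]
        assert all(a > b for a, b in zip(w, w[1:]))

    def test_dispersion_matches_exhaustive_two_partition(self):
        rng = np.random.default_rng(5)
        X, _ = blobs(rng, [(0, 0), (4, 4)], 4, 0.5)  # 8 points
        w_impl, _, _ = within_dispersion(X, 2, seed=0)

        def sse(idx):
            sub = X[list(idx)]
            return ((sub - sub.mean(axis=0)) ** 2).sum()

        best = np.inf
        for r in range(1, 8):
            for grp in itertools.combinations(range(8), r):
                rest = tuple(i for i in range(8) if i not in grp)
                best = min(best, sse(grp) + sse(rest))
        assert w_impl == pytest.approx(best, rel=1e-9)

    def test_reference_count_precondition(self):
        with pytest.raises(ValueError):
            GapStatisticKMeans(B=5).fit(np.zeros((10, 2)))


class TestGaussianMixtureBIC:
    def test_two_blobs_under_every_covariance_family(self):
        rng = np.random.default_rng(6)
        X, _ = blobs(rng, [(0, 0), (8, 0)], 15, 0.4)
        for cov in GaussianMixtureBIC.COV_TYPES:
            est = GaussianMixtureBIC(k_min=1, k_max=5,
                                     covariance_types=(cov,)).fit(X)
            assert est.k_ == 2, cov

    def test_single_component_bic_matches_closed_form(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 2))
        est = GaussianMixtureBIC(k_min=1, k_max=1, covariance_types=("spherical",),
                                 reg_covar=1e-12).fit(X)
        n, d = X.shape
        mu = X.mean(axis=0)
        var = ((X - mu) ** 2).sum() / (n * d)  # MLE spherical variance
        ll = -0.5 * n * d * np.log(2 * np.pi * var) - 0.5 * ((X - mu) ** 2).sum() / var
        hand = ll - 0.5 * (d + 1) * np.log(n)  # d mean params + 1 variance
        assert est.bic_curve_[1] == pytest.approx(hand, rel=1e-9)
        assert gaussian_bic(ll, d + 1, n) == pytest.approx(hand, rel=1e-12)

    def test_two_points_only_evaluates_one_component(self):
        est = GaussianMixtureBIC(k_min=1, k_max=5).fit(np.array([[0.0, 0], [1, 1]]))
        assert list(est.bic_curve_) == [1]
        assert est.k_ == 1


class TestInvariances:
    def test_rigid_motion_and_permutation_leave_selection_unchanged(self):
        rng = np.random.default_rng(8)
        X, _ = blobs(rng, [(0, 0), (5, 1), (2, 6)], 8, 0.3)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        perm = rng.permutation(len(X))
        Xt = (X @ R.T + np.array([3.0, -2.0]))[perm]

        for est_factory in (
            lambda: PAMSilhouette(k_max=6),
            lambda: GapStatisticKMeans(k_max=6, B=30, random_state=0),
            lambda: GaussianMixtureBIC(k_max=6, random_state=0),
        ):
            a = est_factory().fit(X)
            b = est_factory().fit(Xt)
            assert a.k_ == b.k_
            assert adjusted_rand_score(a.labels_[perm], b.labels_) == pytest.approx(1.0)


class TestHaplotypesToSamples:
    def test_agreeing_pair_keeps_label(self):
        labels = np.array([3, 3, 1, 1])
        smap = np.array([0, 0, 1, 1])
        pts = np.array([[0, 0], [0, 0], [5, 5], [5, 5]], dtype=float)
        slab, conflicts = haplotypes_to_samples(labels, smap, points=pts)
        assert slab.tolist() == [3, 1]
        assert conflicts == []

    def test_conflict_resolves_to_nearer_center_and_is_recorded(self):
        labels = np.array([1, 2, 1, 1, 2, 2])
        smap = np.array([0, 0, 1, 1, 2, 2])
        pts = np.array([[0.4, 0], [1.0, 0], [0, 0], [0, 0], [5, 0], [5, 0]],
                       dtype=float)
        slab, conflicts = haplotypes_to_samples(labels, smap, points=pts)
        assert slab[0] == 1  # sample mean (0.7, 0) is nearer center 1 (~0.13,0)
        assert len(conflicts) == 1
        assert conflicts[0]["sample"] == 0 and conflicts[0]["resolved"] == 1


class TestConsensus:
    @staticmethod
    def _embedding(sample_positions, sigma=0.05):
        mu = np.repeat(np.asarray(sample_positions, float), 2, axis=0)
        n = len(sample_positions)
        return LatentEmbedding(
            mu=mu,
            sigma=np.full((2 * n, 2), sigma),
            sample_ids=[f"s{i}" for i in range(n)],
            hap_sample_map=np.repeat(np.arange(n), 2),
        )

    @staticmethod
    def _assignment(method, labels):
        labels = np.asarray(labels)
        return ClusterAssignment(method=method, K=int(labels.max()),
                                 labels=labels, score_curve={})

    def test_majority_with_oversplit_flags(self):
        # 4 tight pairs of samples; one method splits each pair apart but
        # their SD circles overlap -> favored K stays 4 wide with 3 flags...
        pos = [(0, 0), (0.1, 0), (5, 0), (5.1, 0), (0, 5), (0.1, 5), (5, 5), (5.1, 5)]
        emb = self._embedding(pos, sigma=0.2)  # radius 0.2 >> pair separation
        base = [1, 1, 2, 2, 3, 3, 4, 4]
        split = [1, 5, 2, 6, 3, 7, 4, 4]  # three clusters split in two
        rep = consensus(
            [
                self._assignment("pam_silhouette", base),
                self._assignment("gmm_bic", base),
                self._assignment("gap_statistic", split),
            ],
            emb,
        )
        assert rep.favored_K == 4
        assert not rep.no_concordance
        assert len(rep.oversplit_flags) == 3
        assert all(f["method"] == "gap_statistic" for f in rep.oversplit_flags)

    def test_unanimous_small_k_no_flags(self):
        emb = self._embedding([(0, 0), (0, 0.1), (4, 0), (4, 0.1)])
        rep = consensus(
            [self._assignment(m, [1, 1, 2, 2]) for m in ("a", "b", "c")], emb
        )
        assert rep.favored_K == 2
        assert rep.oversplit_flags == []

    def test_total_disagreement_flags_no_concordance(self):
        emb = self._embedding([(i, 0) for i in range(5)], sigma=0.01)
        rep = consensus(
            [
                self._assignment("a", [1, 1, 2, 3, 3]),
                self._assignment("b", [1, 2, 3, 4, 4]),
                self._assignment("c", [1, 2, 3, 4, 5]),
            ],
            emb,
        )
        assert rep.no_concordance
        assert rep.favored_K == 3  # smallest of the disagreeing K values
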