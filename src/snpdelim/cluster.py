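"""Cluster-number selection on latent embeddings.

Three complementary routes to "how many clusters?", all operating on the
low-dimensional latent means produced by the VAE (two haplotype points
per sample):

* :class:`PAMSilhouette` — exact partitioning-around-medoids (build +
  swap) per candidate *k*; the *k* with the highest average silhouette
  width wins.
* :class:`GapStatisticKMeans` — the gap statistic with k-means: compare
  log within-cluster dispersion to its expectation under a uniform
  reference over the data's bounding box, and take the smallest *k* with
  ``Gap(k) >= Gap(k+1) - s_{k+1}``.
* :class:`GaussianMixtureBIC` — Gaussian mixtures over several covariance
  families, initialised from a Ward agglomerative hierarchy, selected by
  BIC (reported on the ``loglik - 0.5 * n_params * log(n)`` scale, higher
  is better).

The three selections are then combined by :func:`consensus`: the modal
*K* is favoured, and any finer split proposed by a dissenting method is
flagged as over-split when its parts' latent SD circles overlap, rather
than silently merged.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from snpdelim._rng import stream_seed
from snpdelim.vae import LatentEmbedding, sd_overlap

__all__ = [
    "ClusterAssignment",
    "ConsensusReport",
    "PAMSilhouette",
    "GapStatisticKMeans",
    "GaussianMixtureBIC",
    "pam_silhouette",
    "gap_statistic",
    "model_based_hierarchical",
    "haplotypes_to_samples",
    "consensus",
    "pam",
    "within_dispersion",
]


@dataclass
class ClusterAssignment:
    """Labels + selected K + the selection-score curve for one method."""

    method: str
    K: int
    labels: np.ndarray                    # per clustered point, values 1..K
    score_curve: dict[int, float]         # k -> selection score
    score_name: str = ""
    centers: np.ndarray | None = None     # medoids / centroids / means
    extras: dict = field(default_factory=dict)

    def validate(self) -> None:
        lab = np.unique(self.labels)
        if lab.min() < 1 or lab.max() > self.K:
            raise ValueError("labels must lie in 1..K")


@dataclass
class ConsensusReport:
    per_method_K: dict[str, int]
    favored_K: int
    oversplit_flags: list[dict]
    no_concordance: bool = False
    removed_samples: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_method_K": self.per_method_K,
            "favored_K": self.favored_K,
            "oversplit_flags": self.oversplit_flags,
            "no_concordance": self.no_concordance,
            "removed_samples": self.removed_samples,
        }


# ---------------------------------------------------------------------------
# PAM (k-medoids, build + swap)
# ---------------------------------------------------------------------------

def pam(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact PAM: greedy BUILD then full SWAP to convergence.

    Returns (labels 0..k-1, medoid indices). Deterministic: ties resolve
    to the lowest index.
    """
    n = len(X)
    D = cdist(X, X)
    # BUILD: first medoid minimises total distance; then greedy additions
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.maximum(dmin[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    # SWAP
    improved = True
    while improved:
        improved = False
        cost = D[:, medoids].min(axis=1).sum()
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                cand = medoids[:mi] + [h] + medoids[mi + 1:]
                delta = D[:, cand].min(axis=1).sum() - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids[mi] = h
            medoids = sorted(medoids)
            improved = True
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, np.array(medoids)


def average_silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width s(i) = (b - a) / max(a, b)."""
    return float(silhouette_score(X, labels, metric="euclidean"))


class PAMSilhouette(BaseEstimator, ClusterMixin):
    """PAM clustering with K chosen by maximum average silhouette width."""

    def __init__(self, k_min: int = 2, k_max: int = 10):
        self.k_min = k_min
        self.k_max = k_max

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = len(X)
        if n < 3:
            raise ValueError("PAM/silhouette selection needs at least 3 points")
        if np.allclose(X, X[0]):
            raise ValueError(
                "all points identical: silhouette (and K) undefined for degenerate input"
            )
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2 (silhouette needs >= 2 clusters)")
        kmax = min(self.k_max, n - 1)
        curve: dict[int, float] = {}
        fits: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for k in range(self.k_min, kmax + 1):
            labels, med = pam(X, k)
            if len(np.unique(labels)) < 2:
                continue
            curve[k] = average_silhouette(X, labels)
            fits[k] = (labels, med)
        if not curve:
            raise ValueError("no valid k in range produced >= 2 clusters")
        self.k_ = max(curve, key=lambda k: (curve[k], -k))
        labels, med = fits[self.k_]
        self.labels_ = labels + 1
        self.medoid_indices_ = med
        self.score_curve_ = curve
        return self

    def assignment_(self, X=None) -> ClusterAssignment:
        return ClusterAssignment(
            method="pam_silhouette",
            K=self.k_,
            labels=self.labels_,
            score_curve=self.score_curve_,
            score_name="average_silhouette_width",
            centers=self.medoid_indices_,
        )


def pam_silhouette(points: np.ndarray, k_range: tuple[int, int] = (2, 10)) -> ClusterAssignment:
    est = PAMSilhouette(k_min=k_range[0], k_max=k_range[1]).fit(points)
    return est.assignment_()


# ---------------------------------------------------------------------------
# gap statistic with k-means
# ---------------------------------------------------------------------------

def within_dispersion(X: np.ndarray, k: int, seed: int, n_init: int = 25) -> tuple[float, np.ndarray, np.ndarray]:
    """W_k = total within-cluster sum of squared distances to centroids.

    k-means with k-means++ initialisation and ``n_init`` restarts; k=1 is
    the dispersion around the grand mean.
    """
    if k == 1:
        mu = X.mean(axis=0, keepdims=True)
        return float(((X - mu) ** 2).sum()), np.zeros(len(X), dtype=int), mu
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return float(km.inertia_), km.labels_, km.cluster_centers_


class GapStatisticKMeans(BaseEstimator, ClusterMixin):
    """Gap-statistic selection of K with k-means clustering.

    ``Gap(k) = E*[log W_k] - log W_k`` with the reference expectation from
    ``B`` uniform draws over the data's bounding box, and
    ``s_k = sd*(log W_k) * sqrt(1 + 1/B)``.

    ``method="firstSEmax"`` (default, the convention of the R clustering
    ecosystem): smallest k whose gap is within one SE of the global
    maximum. ``method="firstmax_se"``: the original smallest k with
    ``Gap(k) >= Gap(k+1) - s_{k+1}`` (k_max if never satisfied), which is
    prone to spurious k=1 when the first two gaps are close.
    """

    def __init__(self, k_min: int = 1, k_max: int = 10, B: int = 100,
                 n_init: int = 25, method: str = "firstSEmax",
                 random_state: int = 0):
        self.k_min = k_min
        self.k_max = k_max
        self.B = B
        self.n_init = n_init
        self.method = method
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.B < 10:
            raise ValueError("B must be >= 10 for a stable reference distribution")
        X = np.asarray(X, dtype=float)
        n = len(X)
        kmax = min(self.k_max, n - 1)
        ks = list(range(self.k_min, kmax + 1))
        logW = {}
        fits = {}
        for k in ks:
            w, lab, cen = within_dispersion(
                X, k, stream_seed(self.random_state, "gap-data", k), self.n_init
            )
            logW[k] = np.log(w) if w > 0 else -np.inf
            fits[k] = (lab, cen)

        lo, hi = X.min(axis=0), X.max(axis=0)
        ref_logW = {k: np.empty(self.B) for k in ks}
        for b in range(self.B):
            rng = np.random.default_rng(stream_seed(self.random_state, "gap-ref", b))
            Xb = rng.uniform(lo, hi, size=X.shape)
            for k in ks:
                w, _, _ = within_dispersion(
                    Xb, k, stream_seed(self.random_state, "gap-ref-km", b * 1000 + k),
                    n_init=max(5, self.n_init // 5),
                )
                ref_logW[k][b] = np.log(w) if w > 0 else -np.inf

        gap = {k: float(ref_logW[k].mean() - logW[k]) for k in ks}
        sk = {
            k: float(ref_logW[k].std(ddof=0) * np.sqrt(1 + 1 / self.B)) for k in ks
        }
        if self.method == "firstSEmax":
            kstar = max(ks, key=lambda k: gap[k])
            thresh = gap[kstar] - sk[kstar]
            self.k_ = next(k for k in ks if gap[k] >= thresh)
        elif self.method == "firstmax_se":
            self.k_ = ks[-1]
            for k in ks[:-1]:
                if gap[k] >= gap[k + 1] - sk[k + 1]:
                    self.k_ = k
                    break
        else:
            raise ValueError(f"unknown gap selection method {self.method!r}")
        lab, cen = fits[self.k_]
        self.labels_ = lab + 1
        self.cluster_centers_ = cen
        self.gap_ = gap
        self.sk_ = sk
        self.log_w_ = {k: float(logW[k]) for k in ks}
        return self

    def assignment_(self) -> ClusterAssignment:
        return ClusterAssignment(
            method="gap_statistic",
            K=self.k_,
            labels=self.labels_,
            score_curve=self.gap_,
            score_name="gap",
            centers=self.cluster_centers_,
            extras={"s_k": self.sk_, "log_W_k": self.log_w_},
        )


def gap_statistic(
    points: np.ndarray,
    k_range: tuple[int, int] = (1, 10),
    B: int = 100,
    seed: int = 0,
) -> ClusterAssignment:
    est = GapStatisticKMeans(
        k_min=k_range[0], k_max=k_range[1], B=B, random_state=seed
    ).fit(points)
    return est.assignment_()


# ---------------------------------------------------------------------------
# model-based (Gaussian mixture) clustering selected by BIC
# ---------------------------------------------------------------------------

def gaussian_bic(loglik: float, n_params: int, n: int) -> float:
    """BIC on the model-based-clustering scale: ll - (p/2) log n (maximise)."""
    return loglik - 0.5 * n_params * np.log(n)


def _gmm_n_params(k: int, d: int, cov: str) -> int:
    means = k * d
    weights = k - 1
    cov_params = {
        "spherical": k,
        "diag": k * d,
        "tied": d * (d + 1) // 2,
        "full": k * d * (d + 1) // 2,
    }[cov]
    return means + weights + cov_params


class GaussianMixtureBIC(BaseEstimator, ClusterMixin):
    """Gaussian-mixture clustering, agglomerative init, BIC-selected K.

    Every candidate (k, covariance family) is fitted by EM initialised
    from a Ward agglomerative partition; the pair maximising
    ``loglik - 0.5 * n_params * log(n)`` is kept. Singular covariances
    are regularised by the ``reg_covar`` floor; the default ``"auto"``
    sets it to ``1e-3`` of the mean per-dimension variance, which blocks
    the unbounded-likelihood degeneracy (a component collapsing onto a
    few near-coincident points) without distorting genuine clusters.
    """

    COV_TYPES = ("spherical", "diag", "tied", "full")

    def __init__(self, k_min: int = 1, k_max: int = 10,
                 covariance_types: tuple[str, ...] = COV_TYPES,
                 reg_covar: float | str = "auto", random_state: int = 0):
        self.k_min = k_min
        self.k_max = k_max
        self.covariance_types = covariance_types
        self.reg_covar = reg_covar
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n, d = X.shape
        if self.reg_covar == "auto":
            reg = max(1e-10, 1e-3 * float(X.var(axis=0).mean()))
        else:
            reg = float(self.reg_covar)
        kmax = max(1, min(self.k_max, n - 1))
        kmin = max(1, self.k_min)
        best = None
        curve: dict[int, float] = {}
        details: dict[tuple[int, str], float] = {}
        for k in range(kmin, kmax + 1):
            if k == 1:
                means_init = X.mean(axis=0, keepdims=True)
            else:
                ward = AgglomerativeClustering(n_clusters=k, linkage="ward").fit(X)
                means_init = np.vstack(
                    [X[ward.labels_ == c].mean(axis=0) for c in range(k)]
                )
            for cov in self.covariance_types:
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type=cov,
                    means_init=means_init,
                    reg_covar=reg,
                    random_state=self.random_state,
                    n_init=1,
                )
                try:
                    gm.fit(X)
                except ValueError:
                    continue
                ll = float(gm.score(X) * n)
                bic = gaussian_bic(ll, _gmm_n_params(k, d, cov), n)
                details[(k, cov)] = bic
                if k not in curve or bic > curve[k]:
                    curve[k] = bic
                if best is None or bic > best[0]:
                    best = (bic, k, cov, gm)
        if best is None:
            raise RuntimeError("no Gaussian mixture could be fitted")
        _, self.k_, self.covariance_type_, gm = best
        self.labels_ = gm.predict(X) + 1
        self.means_ = gm.means_
        self.bic_curve_ = curve
        self.bic_by_model_ = details
        return self

    def assignment_(self) -> ClusterAssignment:
        return ClusterAssignment(
            method="gmm_bic",
            K=self.k_,
            labels=self.labels_,
            score_curve=self.bic_curve_,
            score_name="bic",
            centers=self.means_,
            extras={"covariance_type": self.covariance_type_},
        )


def model_based_hierarchical(
    points: np.ndarray, k_range: tuple[int, int] = (1, 10)
) -> ClusterAssignment:
    est = GaussianMixtureBIC(k_min=k_range[0], k_max=k_range[1]).fit(points)
    return est.assignment_()


# ---------------------------------------------------------------------------
# haplotype -> sample reduction and cross-method consensus
# ---------------------------------------------------------------------------

def haplotypes_to_samples(
    hap_labels: np.ndarray,
    hap_sample_map: np.ndarray,
    points: np.ndarray | None = None,
    centers: np.ndarray | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Reduce per-haplotype labels to per-sample labels.

    Agreeing haplotypes keep their label; disagreements (candidate
    admixture) resolve to the cluster whose centre is nearest to the
    sample's mean position and are returned in the conflict list.
    ``centers[c]`` is the centre of label ``c+1``; computed from
    ``points`` as label means when not given.
    """
    hap_labels = np.asarray(hap_labels)
    hap_sample_map = np.asarray(hap_sample_map)
    n = hap_sample_map.max() + 1
    ks = np.unique(hap_labels)
    if centers is None:
        if points is None:
            raise ValueError("need points or centers to resolve conflicts")
        centers = np.vstack([points[hap_labels == c].mean(axis=0) for c in ks])
    label_index = {c: i for i, c in enumerate(ks)}

    sample_labels = np.zeros(n, dtype=int)
    conflicts: list[dict] = []
    for i in range(n):
        rows = np.nonzero(hap_sample_map == i)[0]
        labs = hap_labels[rows]
        if len(set(labs)) == 1:
            sample_labels[i] = labs[0]
            continue
        pos = points[rows].mean(axis=0)
        cand = sorted(set(labs))
        dists = [np.linalg.norm(pos - centers[label_index[c]]) for c in cand]
        chosen = cand[int(np.argmin(dists))]
        sample_labels[i] = chosen
        conflicts.append({"sample": int(i), "labels": [int(x) for x in labs],
                          "resolved": int(chosen)})
    return sample_labels, conflicts


def _sample_labels_of(a: ClusterAssignment, embedding: LatentEmbedding,
                      points: np.ndarray) -> np.ndarray:
    lab = np.asarray(a.labels)
    if len(lab) == len(embedding.sample_ids):
        return lab
    if len(lab) == len(embedding.hap_sample_map):
        s, _ = haplotypes_to_samples(lab, embedding.hap_sample_map, points=points)
        return s
    raise ValueError(f"{a.method}: label vector matches neither samples nor haplotypes")


def consensus(
    assignments: list[ClusterAssignment],
    embedding: LatentEmbedding,
    removed_samples: list[dict] | None = None,
) -> ConsensusReport:
    """Cross-method consensus with SD-overlap over-splitting flags.

    The favoured K is the modal K across methods (smallest K with a
    "no concordance" flag when all methods disagree). For every method
    reporting a larger K, each reference cluster that the method splits
    into several parts is checked: parts connected through overlapping
    latent SD circles are flagged as probable over-splitting. Flags are
    advisory; nothing is merged silently.
    """
    if len(assignments) < 2:
        raise ValueError("consensus needs at least two assignments")
    per_method = {a.method: a.K for a in assignments}
    counts = Counter(a.K for a in assignments)
    top = counts.most_common()
    no_concordance = top[0][1] == 1
    if no_concordance:
        favored = min(per_method.values())
    else:
        modal_count = top[0][1]
        favored = min(k for k, c in counts.items() if c == modal_count)

    points = embedding.mu
    ref = next(a for a in assignments if a.K == favored)
    ref_sample = _sample_labels_of(ref, embedding, points)

    flags: list[dict] = []
    for a in assignments:
        if a.K <= favored:
            continue
        lab = _sample_labels_of(a, embedding, points)
        for c in np.unique(ref_sample):
            members = np.nonzero(ref_sample == c)[0]
            parts = np.unique(lab[members])
            if len(parts) < 2:
                continue
            for x in range(len(parts)):
                for y in range(x + 1, len(parts)):
                    A = members[lab[members] == parts[x]]
                    Bm = members[lab[members] == parts[y]]
                    if any(sd_overlap(embedding, int(i), int(j)) for i in A for j in Bm):
                        flags.append(
                            {
                                "method": a.method,
                                "reference_cluster": int(c),
                                "split_parts": [int(parts[x]), int(parts[y])],
                                "reason": "parts connected by overlapping latent SDs",
                            }
                        )
    return ConsensusReport(
        per_method_K=per_method,
        favored_K=int(favored),
        oversplit_flags=flags,
        no_concordance=no_concordance,
        removed_samples=removed_samples or [],
    )
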