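"""Bayesian admixture-model clustering (Gibbs sampler) and Evanno delta-K.

The model is the classic admixture model for multilocus genotypes: each
individual *i* carries ancestry proportions ``Q_i`` over *K* clusters
(symmetric Dirichlet(alpha) prior), each cluster *k* carries per-locus
allele frequencies ``P_{k,l}`` (Dirichlet(lambda) prior, independent
across loci — the uncorrelated-frequencies variant), and every allele
copy *c* at locus *l* of individual *i* originates from cluster
``Z ~ Categorical(Q_i)`` and equals allele *a* with probability
``P_{Z,l,a}``. The sampler alternates the conditional draws::

    Z | Q, P   ~  Categorical( Q_{i,k} * P_{k,l,a} )     per allele copy
    P | Z      ~  Dirichlet( lambda + allele counts )    per (k, l)
    Q | Z      ~  Dirichlet( alpha + origin counts )     per individual

Missing allele copies are skipped everywhere. The model evidence for a
given K is estimated from the post-burn-in log-likelihood trace by the
moment estimator ``mean(L) - var(L)/2`` (the convention of the original
admixture-clustering program; an approximation, not a marginal
likelihood). The Evanno method then selects the K where the
replicate-normalised second difference of the evidence,
``Delta K = |L''(K)| / sd(L(K))``, peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator

from snpdelim._rng import substream
from snpdelim.genotypes import MISSING, GenotypeMatrix

__all__ = [
    "AdmixtureConfig",
    "AdmixtureRun",
    "AdmixtureGibbs",
    "EvannoTable",
    "gibbs_admixture",
    "evanno",
    "align_replicates",
]


@dataclass
class AdmixtureConfig:
    """Sampler settings. ``burnin=None`` -> first 10% of iterations."""

    K: int = 2
    iterations: int = 2000
    burnin: int | None = None
    replicates: int = 8
    alpha: float = 1.0
    lam: float = 1.0
    seed: int = 0

    def resolved_burnin(self) -> int:
        return self.iterations // 10 if self.burnin is None else self.burnin

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 <= self.resolved_burnin() < self.iterations:
            raise ValueError("burnin must be < iterations")
        if self.alpha <= 0 or self.lam <= 0:
            raise ValueError("Dirichlet concentrations must be positive")


@dataclass
class AdmixtureRun:
    """Posterior summary of one chain."""

    K: int
    Q: np.ndarray                 # (n, K) posterior-mean ancestry
    P: np.ndarray                 # (K, L, A) posterior-mean frequencies
    Z_counts: np.ndarray          # (n, K) mean origin counts per sweep
    loglik_trace: np.ndarray
    ln_prob_data: float           # mean - var/2 evidence estimate
    sample_ids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")
        if not np.allclose(self.P.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("P simplices must sum to 1")


class AdmixtureGibbs(BaseEstimator):
    """Gibbs sampler for the admixture model (sklearn-style estimator).

    Fit on a :class:`GenotypeMatrix` (haplotype rows = the two allele
    copies per individual). After ``fit``: ``Q_`` (n x K posterior-mean
    ancestry), ``P_`` (K x L x A frequencies), ``loglik_trace_``,
    ``ln_prob_data_`` and ``labels_`` (1..K, max-Q assignment).
    """

    def __init__(self, K: int = 2, iterations: int = 2000, burnin: int | None = None,
                 alpha: float = 1.0, lam: float = 1.0, init: str = "kmeans",
                 random_state: int = 0):
        self.K = K
        self.iterations = iterations
        self.burnin = burnin
        self.alpha = alpha
        self.lam = lam
        self.init = init
        self.random_state = random_state

    @staticmethod
    def _kmeans_init(copies, obs, alleles, K, A, cfg, rng):
        from sklearn.cluster import KMeans

        n, _, L = copies.shape
        # per-sample mean allele dosage, missing imputed with the locus mean
        tot = (alleles * obs).sum(axis=1)          # (n, L)
        cnt = obs.sum(axis=1)
        locus_tot = tot.sum(axis=0)
        locus_cnt = cnt.sum(axis=0)
        locus_mean = np.where(locus_cnt > 0, locus_tot / np.maximum(locus_cnt, 1), 0.5)
        dose = np.where(cnt > 0, tot / np.maximum(cnt, 1), locus_mean[None, :])
        if K == 1:
            lab = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=K, n_init=5,
                        random_state=int(rng.integers(2**31 - 1))).fit(dose)
            lab = km.labels_
        # Q concentrated on the assigned cluster, P from cluster counts
        Q = np.full((n, K), 0.1 / max(K - 1, 1))
        Q[np.arange(n), lab] = 0.9
        Q /= Q.sum(axis=1, keepdims=True)
        cnt = np.zeros((K, L, A))
        for k in range(K):
            sub = np.nonzero(lab == k)[0]
            for a in range(A):
                hit = (alleles[sub] == a) & obs[sub]
                cnt[k, :, a] = hit.sum(axis=(0, 1))
        g = rng.gamma(cfg.lam + cnt)
        P = g / g.sum(axis=2, keepdims=True)
        return Q, P

    def _config(self) -> AdmixtureConfig:
        return AdmixtureConfig(
            K=self.K, iterations=self.iterations, burnin=self.burnin,
            alpha=self.alpha, lam=self.lam, seed=self.random_state,
        )

    def fit(self, X: GenotypeMatrix, y=None):
        cfg = self._config()
        cfg.validate()
        if isinstance(X, GenotypeMatrix):
            hap = X.haplotypes
            sample_ids = list(X.sample_ids)
        else:
            hap = np.asarray(X, dtype=np.int16)
            sample_ids = [f"S{i}" for i in range(hap.shape[0] // 2)]
        n = hap.shape[0] // 2
        L = hap.shape[1]
        copies = hap.reshape(n, 2, L)
        obs = copies != MISSING
        A = max(int(copies[obs].max()) + 1, 2) if obs.any() else 2
        alleles = np.where(obs, copies, 0)  # placeholder 0 at missing (masked out)

        K = cfg.K
        rng = substream(cfg.seed, "gibbs")
        burn = cfg.resolved_burnin()

        # init: flat prior draws, or a k-means warm start (default) that
        # places each chain in the basin of a genuine mode — short chains
        # at higher K otherwise stall in poor modes, inflating the
        # replicate spread of the evidence exactly where delta-K looks
        if self.init == "kmeans":
            Q, P = self._kmeans_init(copies, obs, alleles, K, A, cfg, rng)
        elif self.init == "prior":
            Q = rng.dirichlet(np.full(K, cfg.alpha), size=n)
            P = rng.dirichlet(np.full(A, cfg.lam), size=(K, L))
        else:
            raise ValueError(f"unknown init {self.init!r}")

        l_idx = np.arange(L)[None, None, :]
        loglik = np.empty(cfg.iterations)
        Q_acc = np.zeros((n, K))
        P_acc = np.zeros((K, L, A))
        Z_acc = np.zeros((n, K))
        kept = 0

        for it in range(cfg.iterations):
            # P(copy from k) prop. to q_ik * p_k,l,a  -> (n, 2, L, K)
            P_alk = P.transpose(1, 2, 0)              # (L, A, K)
            w = Q[:, None, None, :] * P_alk[l_idx, alleles]
            w[~obs] = 1.0                              # dummy; excluded from counts
            tot = w.sum(axis=3, keepdims=True)
            ll = float(np.log(tot[..., 0][obs]).sum())
            if not np.isfinite(ll):
                raise FloatingPointError(f"non-finite log-likelihood at sweep {it}")
            loglik[it] = ll

            cdf = np.cumsum(w, axis=3) / tot
            u = rng.random((n, 2, L, 1))
            Z = (u > cdf).sum(axis=3)                  # (n, 2, L) in 0..K-1

            # allele counts per (k, l, a), observed copies only
            zz = Z[obs]
            ll_sites = np.broadcast_to(np.arange(L)[None, None, :], Z.shape)[obs]
            aa = alleles[obs]
            cnt_P = np.zeros((K, L, A))
            np.add.at(cnt_P, (zz, ll_sites, aa), 1.0)

            # origin counts per (i, k)
            ii = np.broadcast_to(np.arange(n)[:, None, None], Z.shape)[obs]
            cnt_Q = np.zeros((n, K))
            np.add.at(cnt_Q, (ii, zz), 1.0)

            # conjugate Dirichlet draws via normalised gammas
            gP = rng.gamma(cfg.lam + cnt_P)
            P = gP / gP.sum(axis=2, keepdims=True)
            P = np.clip(P, 1e-300, None)
            P /= P.sum(axis=2, keepdims=True)
            gQ = rng.gamma(cfg.alpha + cnt_Q)
            Q = gQ / gQ.sum(axis=1, keepdims=True)

            if it >= burn:
                Q_acc += Q
                P_acc += P
                Z_acc += cnt_Q
                kept += 1

        post = loglik[burn:]
        ln_prob = float(post.mean() - post.var(ddof=1) / 2) if len(post) > 1 else float(post.mean())

        self.Q_ = Q_acc / kept
        self.Q_ /= self.Q_.sum(axis=1, keepdims=True)
        self.P_ = P_acc / kept
        self.P_ /= self.P_.sum(axis=2, keepdims=True)
        self.Z_counts_ = Z_acc / kept
        self.loglik_trace_ = loglik
        self.ln_prob_data_ = ln_prob
        self.labels_ = np.argmax(self.Q_, axis=1) + 1
        self.sample_ids_ = sample_ids
        return self

    def run_(self) -> AdmixtureRun:
        run = AdmixtureRun(
            K=self.K, Q=self.Q_, P=self.P_, Z_counts=self.Z_counts_,
            loglik_trace=self.loglik_trace_, ln_prob_data=self.ln_prob_data_,
            sample_ids=self.sample_ids_,
        )
        run.validate()
        return run


def gibbs_admixture(gm: GenotypeMatrix, config: AdmixtureConfig) -> AdmixtureRun:
    """One chain of the admixture Gibbs sampler on an unlinked-SNP matrix."""
    est = AdmixtureGibbs(
        K=config.K, iterations=config.iterations, burnin=config.burnin,
        alpha=config.alpha, lam=config.lam, random_state=config.seed,
    ).fit(gm)
    return est.run_()


# ---------------------------------------------------------------------------
# replicate alignment (label switching)
# ---------------------------------------------------------------------------

def align_replicates(Q_list: list[np.ndarray]) -> tuple[list[np.ndarray], np.ndarray]:
    """Permute each replicate's cluster columns to match the first.

    Label switching makes raw Q columns incomparable between chains; each
    replicate's columns are permuted by the optimal assignment minimising
    the total absolute difference to the first replicate. Returns the
    aligned matrices and their element-wise mean.
    """
    if not Q_list:
        raise ValueError("no Q matrices")
    shapes = {q.shape for q in Q_list}
    if len(shapes) != 1:
        raise ValueError(f"mismatched Q shapes: {sorted(shapes)}")
    ref = Q_list[0]
    K = ref.shape[1]
    aligned = [ref.copy()]
    for q in Q_list[1:]:
        cost = np.abs(ref[:, :, None] - q[:, None, :]).sum(axis=0)  # (K_ref, K_rep)
        _, perm = linear_sum_assignment(cost)
        aligned.append(q[:, perm])
    return aligned, np.mean(aligned, axis=0)


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

@dataclass
class EvannoTable:
    """Per-K evidence summary and the delta-K selection curve.

    ``delta_K[K] = |L''(K)| / sd(L(K))`` with
    ``L'(K) = L(K) - L(K-1)`` and ``L''(K) = L'(K+1) - L'(K)``; defined
    only for interior K. ``sd = 0`` yields +inf with a warning.
    """

    K_values: list[int]
    mean_L: dict[int, float]
    sd_L: dict[int, float]
    L_prime: dict[int, float]
    L_doubleprime_abs: dict[int, float]
    delta_K: dict[int, float]
    optimal_K: int

    def to_frame(self):
        import pandas as pd

        rows = []
        for k in self.K_values:
            rows.append(
                {
                    "K": k,
                    "mean_L": self.mean_L[k],
                    "sd_L": self.sd_L[k],
                    "L_prime": self.L_prime.get(k, np.nan),
                    "abs_L_doubleprime": self.L_doubleprime_abs.get(k, np.nan),
                    "delta_K": self.delta_K.get(k, np.nan),
                }
            )
        return pd.DataFrame(rows)


def evanno(runs_by_K: dict[int, list]) -> EvannoTable:
    """Evanno delta-K table from replicated evidence estimates.

    ``runs_by_K`` maps K to a list (>= 2 entries for an sd) of either
    :class:`AdmixtureRun` objects or plain ``ln P(X|K)`` floats, over at
    least 3 consecutive K values.
    """
    ks = sorted(runs_by_K)
    if len(ks) < 3:
        raise ValueError("Evanno delta-K needs at least 3 K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError(f"K values must be consecutive, got {ks}")

    def as_floats(v) -> np.ndarray:
        return np.array(
            [x.ln_prob_data if isinstance(x, AdmixtureRun) else float(x) for x in v]
        )

    L = {k: as_floats(runs_by_K[k]) for k in ks}
    for k in ks:
        if len(L[k]) < 2:
            raise ValueError(f"K={k}: need >= 2 replicates for an sd")
    mean_L = {k: float(L[k].mean()) for k in ks}
    sd_L = {k: float(L[k].std(ddof=1)) for k in ks}
    L_prime = {k: mean_L[k] - mean_L[k - 1] for k in ks[1:]}
    L_dp = {k: abs(L_prime[k + 1] - L_prime[k]) for k in ks[1:-1]}
    delta = {}
    for k in ks[1:-1]:
        if sd_L[k] == 0:
            if L_dp[k] == 0:
                delta[k] = 0.0  # flat evidence curve: no signal at this K
            else:
                warnings.warn(f"K={k}: zero sd across replicates; delta-K is +inf")
                delta[k] = float("inf")
        else:
            delta[k] = L_dp[k] / sd_L[k]
    optimal = max(delta, key=lambda k: (delta[k], -k))
    return EvannoTable(
        K_values=ks, mean_L=mean_L, sd_L=sd_L, L_prime=L_prime,
        L_doubleprime_abs=L_dp, delta_K=delta, optimal_K=int(optimal),
    )
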