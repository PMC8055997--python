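"""Variational-autoencoder embedding of haplotypes.

Haplotype rows are one-hot encoded (one unit vector per observed site,
all-zeros per missing site) and compressed to a low-dimensional Gaussian
latent space by a small dense VAE. Each haplotype receives a latent mean
``mu`` and standard deviation ``sigma``; plotting both per sample (two
haplotype points each) is the standard visual for SNP-based species
delimitation, and the sigma circles feed the SD-overlap over-splitting
check used downstream.

The VAE is a plain numpy implementation (two ELU hidden layers each side,
reparameterised diagonal-Gaussian posterior, Adam): the datasets this
package targets are tens of haplotypes by a few thousand sites, where a
full-batch dense network trains in seconds on one CPU.

Training loss = masked categorical cross-entropy (missing sites excluded
entirely) + KL divergence of the posterior from N(0, I), averaged over
haplotypes. Several independently initialised replicates are trained and
the one with the lowest average loss over the post-burn-in epochs is kept,
mirroring the burn-in convention of Bayesian MCMC summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from snpdelim._rng import substream
from snpdelim.genotypes import GenotypeMatrix

__all__ = [
    "OneHotTensor",
    "VaeConfig",
    "TrainingTrace",
    "LatentEmbedding",
    "VAEEmbedder",
    "one_hot_encode",
    "train_vae",
    "replicate_select",
    "sd_overlap",
]


# ---------------------------------------------------------------------------
# one-hot encoding
# ---------------------------------------------------------------------------

@dataclass
class OneHotTensor:
    """One-hot haplotype tensor.

    ``values[h, s]`` is the unit vector of haplotype *h*'s allele at site
    *s* (state order = ascending allele code 0, 1, 2, ...), or all zeros
    where the call is missing; ``observed_mask[h, s]`` is True where a
    call exists.
    """

    values: np.ndarray           # (H, S, A) float32
    observed_mask: np.ndarray    # (H, S) bool
    sample_ids: list[str]
    hap_sample_map: np.ndarray   # (H,) sample index per haplotype row

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_sites(self) -> int:
        return self.values.shape[1]

    @property
    def n_states(self) -> int:
        return self.values.shape[2]

    def validate(self) -> None:
        sums = self.values.sum(axis=2)
        if not np.allclose(sums, self.observed_mask.astype(float)):
            raise ValueError("state-axis sums must equal the observed mask")


def one_hot_encode(gm: GenotypeMatrix, n_states: int | None = None) -> OneHotTensor:
    """Encode a genotype matrix as an :class:`OneHotTensor`.

    ``n_states`` defaults to ``max observed allele code + 1`` (2 for
    biallelic, 4 for nucleotide-coded data).
    """
    A = int(n_states) if n_states is not None else max(gm.n_states, 2)
    obs = ~gm.missing_mask
    H, S = gm.haplotypes.shape
    values = np.zeros((H, S, A), dtype=np.float32)
    rows, cols = np.nonzero(obs)
    values[rows, cols, gm.haplotypes[rows, cols]] = 1.0
    return OneHotTensor(
        values=values,
        observed_mask=obs,
        sample_ids=list(gm.sample_ids),
        hap_sample_map=gm.hap_sample_map(),
    )


# ---------------------------------------------------------------------------
# configuration / outputs
# ---------------------------------------------------------------------------

@dataclass
class VaeConfig:
    """Training configuration. ``hidden=None`` -> (max(64, S/10), 32)."""

    latent_dim: int = 2
    hidden: tuple[int, int] | None = None
    epochs: int = 500
    learning_rate: float = 1e-3
    kl_weight: float | str = "auto"
    replicates: int = 5
    burnin_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0 < self.burnin_fraction < 1:
            raise ValueError("burnin_fraction must be in (0, 1)")
        if self.epochs < 1 or self.replicates < 1:
            raise ValueError("epochs and replicates must be positive")
        if self.kl_weight != "auto" and self.kl_weight <= 0:
            raise ValueError("kl_weight must be positive or 'auto'")


@dataclass
class TrainingTrace:
    loss: np.ndarray       # per-epoch total loss (reconstruction + KL)
    replicate: int

    def validate(self) -> None:
        if not np.isfinite(self.loss).all():
            raise ValueError("non-finite loss in trace")


@dataclass
class LatentEmbedding:
    """Per-haplotype latent means and standard deviations."""

    mu: np.ndarray               # (H, d)
    sigma: np.ndarray            # (H, d), strictly positive
    sample_ids: list[str]
    hap_sample_map: np.ndarray   # (H,)

    def validate(self) -> None:
        if (self.sigma <= 0).any():
            raise ValueError("sigma must be strictly positive")
        counts = np.bincount(self.hap_sample_map, minlength=len(self.sample_ids))
        if not (counts == 2).all():
            raise ValueError("each sample must have exactly two haplotypes")

    def sample_means(self) -> np.ndarray:
        """(n_samples, d) mean of the two haplotype mu positions."""
        n = len(self.sample_ids)
        out = np.zeros((n, self.mu.shape[1]))
        np.add.at(out, self.hap_sample_map, self.mu)
        return out / 2.0

    def sample_radii(self) -> np.ndarray:
        """Per sample: mean over its haplotypes of ||sigma|| / sqrt(d)."""
        d = self.sigma.shape[1]
        r_hap = np.linalg.norm(self.sigma, axis=1) / math.sqrt(d)
        n = len(self.sample_ids)
        out = np.zeros(n)
        np.add.at(out, self.hap_sample_map, r_hap)
        return out / 2.0

    def to_frame(self):
        import pandas as pd

        d = self.mu.shape[1]
        cols = {"sample": [self.sample_ids[i] for i in self.hap_sample_map]}
        for j in range(d):
            cols[f"mu{j}"] = self.mu[:, j]
        for j in range(d):
            cols[f"sigma{j}"] = self.sigma[:, j]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _elu(x):
    return np.where(x > 0, x, np.expm1(x))


def _delu(x):
    return np.where(x > 0, 1.0, np.exp(x))


class _Adam:
    def __init__(self, params, lr):
        self.lr, self.b1, self.b2, self.eps = lr, 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _glorot(rng, fan_in, fan_out):
    lim = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out)).astype(np.float32)


def kl_standard_normal(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Per-row KL( N(mu, diag sigma^2) || N(0, I) ).

    Closed form: -1/2 sum_d (1 + log sigma^2 - mu^2 - sigma^2).
    """
    mu = np.atleast_2d(mu)
    sigma = np.atleast_2d(sigma)
    return -0.5 * np.sum(1 + 2 * np.log(sigma) - mu**2 - sigma**2, axis=1)


class _VaeNet:
    """Dense VAE with manual gradients (full batch)."""

    def __init__(self, D, h1, h2, d, rng):
        self.D, self.h1, self.h2, self.d = D, h1, h2, d
        z32 = lambda *s: np.zeros(s, dtype=np.float32)
        self.params = [
            _glorot(rng, D, h1), z32(h1),          # W1 b1
            _glorot(rng, h1, h2), z32(h2),         # W2 b2
            _glorot(rng, h2, d), z32(d),           # Wm bm
            _glorot(rng, h2, d), z32(d),           # Wv bv
            _glorot(rng, d, h2), z32(h2),          # W3 b3
            _glorot(rng, h2, h1), z32(h1),         # W4 b4
            _glorot(rng, h1, D), z32(D),           # W5 b5
        ]

    def encode(self, X):
        W1, b1, W2, b2, Wm, bm, Wv, bv = self.params[:8]
        p1 = X @ W1 + b1
        a1 = _elu(p1)
        p2 = a1 @ W2 + b2
        a2 = _elu(p2)
        mu = a2 @ Wm + bm
        logvar = np.clip(a2 @ Wv + bv, -10, 10)
        return p1, a1, p2, a2, mu, logvar

    def decode(self, z):
        W3, b3, W4, b4, W5, b5 = self.params[8:]
        p3 = z @ W3 + b3
        a3 = _elu(p3)
        p4 = a3 @ W4 + b4
        a4 = _elu(p4)
        logits = a4 @ W5 + b5
        return p3, a3, p4, a4, logits

    def loss_and_grads(self, X, target3, obs_mask, eps, kl_weight=1.0):
        """One full-batch forward/backward pass.

        X: (H, D) flattened one-hot input; target3: (H, S, A); obs_mask:
        (H, S); eps: (H, d) reparameterisation noise. Returns (mean total
        loss, mean recon, mean KL, grads).
        """
        H, S, A = target3.shape
        p1, a1, p2, a2, mu, logvar = self.encode(X)
        sig = np.exp(0.5 * logvar)
        z = mu + sig * eps
        p3, a3, p4, a4, logits = self.decode(z)

        lg = logits.reshape(H, S, A)
        lg = lg - lg.max(axis=2, keepdims=True)
        ex = np.exp(lg)
        prob = ex / ex.sum(axis=2, keepdims=True)
        logp = lg - np.log(ex.sum(axis=2, keepdims=True))
        recon_i = -(target3 * logp).sum(axis=2)         # (H, S)
        recon_i = (recon_i * obs_mask).sum(axis=1)      # (H,)
        kl_i = -0.5 * np.sum(1 + logvar - mu**2 - np.exp(logvar), axis=1)
        loss = float(np.mean(recon_i + kl_weight * kl_i))

        # ---- backward ----
        dlogits = (prob * obs_mask[:, :, None] - target3 * obs_mask[:, :, None])
        dlogits = dlogits.reshape(H, S * A).astype(np.float32) / H

        W1, b1, W2, b2, Wm, bm, Wv, bv, W3, b3, W4, b4, W5, b5 = self.params
        dW5 = a4.T @ dlogits
        db5 = dlogits.sum(0)
        da4 = dlogits @ W5.T
        dp4 = da4 * _delu(p4)
        dW4 = a3.T @ dp4
        db4 = dp4.sum(0)
        da3 = dp4 @ W4.T
        dp3 = da3 * _delu(p3)
        dW3 = z.T @ dp3
        db3 = dp3.sum(0)
        dz = dp3 @ W3.T

        dmu = dz + kl_weight * mu / H
        dlogvar = dz * eps * 0.5 * sig + kl_weight * 0.5 * (np.exp(logvar) - 1.0) / H
        dWm = a2.T @ dmu
        dbm = dmu.sum(0)
        dWv = a2.T @ dlogvar
        dbv = dlogvar.sum(0)
        da2 = dmu @ Wm.T + dlogvar @ Wv.T
        dp2 = da2 * _delu(p2)
        dW2 = a1.T @ dp2
        db2 = dp2.sum(0)
        da1 = dp2 @ W2.T
        dp1 = da1 * _delu(p1)
        dW1 = X.T @ dp1
        db1 = dp1.sum(0)

        grads = [dW1, db1, dW2, db2, dWm, dbm, dWv, dbv,
                 dW3, db3, dW4, db4, dW5, db5]
        grads = [g.astype(np.float32) for g in grads]
        return loss, float(np.mean(recon_i)), float(np.mean(kl_i)), grads


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class VAEEmbedder(BaseEstimator, TransformerMixin):
    """Replicated VAE embedding of one-hot haplotypes (sklearn-style).

    Parameters
    ----------
    latent_dim : latent dimensionality (2 for the standard plot).
    hidden : encoder widths ``(h1, h2)``; None -> ``(max(64, S // 10), 32)``.
    epochs : full-batch training epochs per replicate.
    learning_rate : Adam step size.
    replicates : independently initialised training runs.
    burnin_fraction : fraction of epochs discarded before averaging the
        loss used to pick the best replicate.
    random_state : seed for initialisation and reparameterisation noise.

    Attributes (after :meth:`fit`)
    ------------------------------
    embedding_ : :class:`LatentEmbedding` of the selected replicate.
    traces_ : list of :class:`TrainingTrace`, one per surviving replicate.
    selected_replicate_ : index into ``traces_`` chosen by the burn-in rule.
    """

    def __init__(
        self,
        latent_dim: int = 2,
        hidden: tuple[int, int] | None = None,
        epochs: int = 500,
        learning_rate: float = 1e-3,
        kl_weight: float | str = "auto",
        replicates: int = 5,
        burnin_fraction: float = 0.5,
        random_state: int = 0,
    ):
        self.latent_dim = latent_dim
        self.hidden = hidden
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.kl_weight = kl_weight
        self.replicates = replicates
        self.burnin_fraction = burnin_fraction
        self.random_state = random_state

    # -- internals ------------------------------------------------------
    def _resolve_hidden(self, n_sites: int) -> tuple[int, int]:
        if self.hidden is not None:
            return tuple(self.hidden)
        return max(64, n_sites // 10), 32

    def _resolve_kl_weight(self, n_sites: int) -> float:
        # "auto" scales the KL term with the site count so the shrinkage
        # toward N(0, I) keeps a constant strength relative to the
        # reconstruction signal, which grows linearly in sites.
        if self.kl_weight == "auto":
            return max(1.0, 0.02 * n_sites)
        return float(self.kl_weight)

    def _train_one(self, tensor: OneHotTensor, rep: int):
        H, S, A = tensor.values.shape
        D = S * A
        h1, h2 = self._resolve_hidden(S)
        rng = substream(self.random_state, "vae-replicate", rep)
        net = _VaeNet(D, h1, h2, self.latent_dim, rng)
        X = tensor.values.reshape(H, D)
        t3 = tensor.values
        obs = tensor.observed_mask
        opt = _Adam(net.params, self.learning_rate)
        losses = np.empty(self.epochs)
        for ep in range(self.epochs):
            eps = rng.standard_normal((H, self.latent_dim)).astype(np.float32)
            loss, _, _, grads = net.loss_and_grads(X, t3, obs, eps, self._resolve_kl_weight(S))
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"replicate {rep}: non-finite loss at epoch {ep}"
                )
            opt.step(net.params, grads)
            losses[ep] = loss
        _, _, _, _, mu, logvar = net.encode(X)
        sigma = np.exp(0.5 * logvar)
        return mu.astype(float), sigma.astype(float), TrainingTrace(losses, rep)

    # -- sklearn surface ------------------------------------------------
    def fit(self, X: OneHotTensor | GenotypeMatrix, y=None):
        VaeConfig(
            latent_dim=self.latent_dim,
            hidden=self.hidden,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            kl_weight=self.kl_weight,
            replicates=self.replicates,
            burnin_fraction=self.burnin_fraction,
            seed=self.random_state,
        ).validate()
        tensor = one_hot_encode(X) if isinstance(X, GenotypeMatrix) else X
        tensor.validate()

        results, traces = [], []
        for rep in range(self.replicates):
            try:
                mu, sigma, trace = self._train_one(tensor, rep)
            except FloatingPointError as err:
                warnings.warn(f"VAE replicate aborted: {err}", RuntimeWarning)
                continue
            results.append((mu, sigma))
            traces.append(trace)
        if not results:
            raise RuntimeError("all VAE replicates diverged (non-finite loss)")

        best = replicate_select(traces, self.burnin_fraction)
        mu, sigma = results[best]
        self.traces_ = traces
        self.selected_replicate_ = best
        self.embedding_ = LatentEmbedding(
            mu=mu,
            sigma=sigma,
            sample_ids=list(tensor.sample_ids),
            hap_sample_map=tensor.hap_sample_map,
        )
        self.embedding_.validate()
        return self

    def transform(self, X: OneHotTensor | GenotypeMatrix | None = None) -> np.ndarray:
        """Latent means of the fitted data (the embedding is transductive)."""
        check_is_fitted(self, "embedding_")
        return self.embedding_.mu

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform()


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------

def train_vae(
    tensor: OneHotTensor, config: VaeConfig | None = None
) -> tuple[LatentEmbedding, TrainingTrace]:
    """Train ``config.replicates`` VAEs and return the selected one."""
    config = config or VaeConfig()
    config.validate()
    est = VAEEmbedder(
        latent_dim=config.latent_dim,
        hidden=config.hidden,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        kl_weight=config.kl_weight,
        replicates=config.replicates,
        burnin_fraction=config.burnin_fraction,
        random_state=config.seed,
    ).fit(tensor)
    return est.embedding_, est.traces_[est.selected_replicate_]


def replicate_select(traces: list[TrainingTrace], burnin_fraction: float = 0.5) -> int:
    """Index of the replicate with the lowest mean post-burn-in loss.

    The first ``ceil(burnin_fraction * epochs)`` epochs are discarded and
    the remaining losses averaged; ties resolve to the lowest replicate
    index (and are logged).
    """
    if not traces:
        raise ValueError("no traces to select from")
    lengths = {len(t.loss) for t in traces}
    if len(lengths) != 1:
        raise ValueError("traces must have equal length")
    T = lengths.pop()
    if not 0 < burnin_fraction < 1:
        raise ValueError("burnin_fraction must be in (0, 1)")
    start = math.ceil(burnin_fraction * T)
    means = np.array([float(np.mean(t.loss[start:])) for t in traces])
    best = int(np.argmin(means))
    if (means == means[best]).sum() > 1:
        warnings.warn("replicate selection tie; keeping the lowest index")
    return best


def sd_overlap(
    embedding: LatentEmbedding, sample_i: int | str, sample_j: int | str
) -> bool:
    """Do two samples' latent SD circles overlap?

    Each sample is summarised by the mean position of its two haplotypes
    and a radius ``r`` = mean over haplotypes of ``||sigma|| / sqrt(d)``;
    the samples overlap iff the distance between their mean positions is
    at most ``r_i + r_j``. Reflexive by construction.
    """
    idx = {}
    for s in (sample_i, sample_j):
        if isinstance(s, str):
            idx[s] = embedding.sample_ids.index(s)
        else:
            idx[s] = int(s)
    i, j = idx[sample_i], idx[sample_j]
    means = embedding.sample_means()
    radii = embedding.sample_radii()
    return bool(np.linalg.norm(means[i] - means[j]) <= radii[i] + radii[j])
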