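"""Structured-population SNP simulator with ground truth.

Generates diploid biallelic genotype matrices with the statistical
structure the delimitation analysis assumes: *K* populations drifted from
a shared ancestral allele-frequency vector under the Balding–Nichols
F-model, optional admixture via a symmetric Dirichlet over ancestry
proportions, optional weakly diverged sister lineages ("cryptic"
complexes), and missing-completely-at-random masking at the haplotype x
site entry level.

Model
-----
Per locus *l*: ancestral frequency ``p_l ~ Uniform(0.05, 0.95)``; for
population *k* with drift parameter ``F_k``::

    p_{k,l} ~ Beta(p_l (1 - F_k) / F_k,  (1 - p_l)(1 - F_k) / F_k)

``F_k`` plays the role of an FST-like divergence from the ancestral pool.
Each haplotype copy of individual *i* draws its source population from the
individual's ancestry row ``Q_i`` and then its allele
``~ Bernoulli(p_{k,l})``. Defaults mirror a typical ddRADseq
species-delimitation matrix: a few dozen diploids, thousands of loci, and
~40% missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from snpdelim._rng import substream
from snpdelim.genotypes import MISSING, GenotypeMatrix

__all__ = ["PopModel", "SimTruth", "simulate", "make_cryptic_complex"]

_F_MAX = 0.999


@dataclass
class PopModel:
    """Parameters of one simulated structured population draw.

    ``admix_alpha = 0`` means every individual is a pure member of its
    population; ``admix_alpha > 0`` draws each individual's ancestry row
    from ``Dirichlet(alpha, ..., alpha)`` centred on its home population
    (home component weighted up by ``1/alpha`` relative weight retained
    via the concentration on all components — small alpha keeps rows near
    the simplex corners, large alpha mixes them).
    """

    K_true: int = 4
    n_per_pop: int = 8
    L: int = 5000
    F_per_pop: tuple[float, ...] | float = 0.2
    admix_alpha: float = 0.0
    missing_rate: float = 0.40
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    seed: int = 0

    def f_vector(self) -> np.ndarray:
        f = np.broadcast_to(np.asarray(self.F_per_pop, dtype=float), (self.K_true,))
        return f.copy()

    def validate(self) -> None:
        if self.K_true < 1:
            raise ValueError("K_true must be >= 1")
        if self.n_per_pop < 1 or self.L < 1:
            raise ValueError("n_per_pop and L must be positive")
        f = self.f_vector()
        if (f < 0).any():
            raise ValueError("F must be >= 0")
        if (f > _F_MAX).any():
            raise ValueError(f"F above {_F_MAX} is rejected (degenerate drift)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.admix_alpha < 0:
            raise ValueError("admix_alpha must be >= 0")
        if not 0 < self.ancestral_low < self.ancestral_high < 1:
            raise ValueError("ancestral frequency bounds must satisfy 0 < low < high < 1")


@dataclass
class SimTruth:
    """Ground truth for parameter-recovery tests."""

    true_label: np.ndarray          # (n,) home population per sample
    Q_true: np.ndarray              # (n, K) ancestry proportions
    ancestral_freqs: np.ndarray     # (L,)
    pop_freqs: np.ndarray           # (K, L)

    def validate(self) -> None:
        if not np.allclose(self.Q_true.sum(axis=1), 1.0):
            raise ValueError("Q_true rows must sum to 1")
        for arr in (self.ancestral_freqs, self.pop_freqs):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError("frequencies must lie in [0, 1]")


def _pop_freqs(anc: np.ndarray, f: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    K, L = len(f), len(anc)
    out = np.empty((K, L))
    for k in range(K):
        if f[k] < 1e-12:
            out[k] = anc  # no-drift limit
        else:
            a = anc * (1 - f[k]) / f[k]
            b = (1 - anc) * (1 - f[k]) / f[k]
            out[k] = rng.beta(a, b)
    return out


def simulate(model: PopModel) -> tuple[GenotypeMatrix, SimTruth]:
    """Draw one genotype matrix plus ground truth from ``model``.

    Sub-streams ("freqs", "admixture", "genotypes", "mask") are derived
    from ``model.seed`` so each stage is independently reproducible.
    """
    model.validate()
    K, n_per, L = model.K_true, model.n_per_pop, model.L
    n = K * n_per
    f = model.f_vector()

    rng_f = substream(model.seed, "freqs")
    anc = rng_f.uniform(model.ancestral_low, model.ancestral_high, size=L)
    pop_freqs = _pop_freqs(anc, f, rng_f)

    labels = np.repeat(np.arange(K), n_per)
    rng_q = substream(model.seed, "admixture")
    if model.admix_alpha > 0:
        Q = rng_q.dirichlet(np.full(K, model.admix_alpha), size=n)
        # anchor each individual to its home population so true_label stays meaningful
        Q = 0.5 * Q + 0.5 * np.eye(K)[labels]
    else:
        Q = np.eye(K)[labels]

    rng_g = substream(model.seed, "genotypes")
    # source population of every haplotype copy at every locus: (n, 2, L)
    u = rng_g.random((n, 2, L, 1))
    cdf = np.cumsum(Q, axis=1)[:, None, None, :]
    src = (u > cdf).sum(axis=3)
    alleles = rng_g.random((n, 2, L)) < pop_freqs[src, np.arange(L)[None, None, :]]
    # row order (i0 copy0, i0 copy1, i1 copy0, ...): rows 2i, 2i+1 = sample i
    hap = alleles.reshape(2 * n, L).astype(np.int16)

    rng_m = substream(model.seed, "mask")
    if model.missing_rate > 0:
        mask = rng_m.random((2 * n, L)) < model.missing_rate
        hap[mask] = MISSING

    gm = GenotypeMatrix(
        sample_ids=[f"S{labels[i]}_{i:03d}" for i in range(n)],
        haplotypes=hap.astype(np.int16),
        locus_of_site=[f"L{j}" for j in range(L)],
        populations=[f"pop{k}" for k in labels],
    )
    truth = SimTruth(
        true_label=labels, Q_true=Q, ancestral_freqs=anc, pop_freqs=pop_freqs
    )
    truth.validate()
    return gm, truth


def make_cryptic_complex(
    base_model: PopModel, split_F: float
) -> tuple[GenotypeMatrix, SimTruth]:
    """Replace the last population with two weakly diverged daughters.

    The daughters drift from the parent's (already drifted) frequency
    vector by ``split_F`` via the same Beta construction, emulating a
    complex of recently separated sister lineages. Requires
    ``split_F < min(F_per_pop)`` so the split is shallower than the
    between-species divergence. Output has ``K_true + 1`` true labels.
    """
    base_model.validate()
    f = base_model.f_vector()
    if not 0 <= split_F < f.min():
        raise ValueError("split_F must satisfy 0 <= split_F < min(F_per_pop)")

    # simulate K+1 populations, then overwrite the two daughters' frequencies
    ext = replace(
        base_model,
        K_true=base_model.K_true + 1,
        F_per_pop=tuple(f) + (f[-1],),
    )
    K, L = ext.K_true, ext.L

    rng_f = substream(ext.seed, "freqs")
    anc = rng_f.uniform(ext.ancestral_low, ext.ancestral_high, size=L)
    pop_freqs = _pop_freqs(anc, ext.f_vector(), rng_f)
    rng_split = substream(ext.seed, "cryptic-split")
    parent = pop_freqs[K - 2].clip(1e-6, 1 - 1e-6)
    for d in (K - 2, K - 1):
        if split_F < 1e-12:
            pop_freqs[d] = parent
        else:
            a = parent * (1 - split_F) / split_F
            b = (1 - parent) * (1 - split_F) / split_F
            pop_freqs[d] = rng_split.beta(a, b)

    n = K * ext.n_per_pop
    labels = np.repeat(np.arange(K), ext.n_per_pop)
    rng_q = substream(ext.seed, "admixture")
    if ext.admix_alpha > 0:
        Q = rng_q.dirichlet(np.full(K, ext.admix_alpha), size=n)
        Q = 0.5 * Q + 0.5 * np.eye(K)[labels]
    else:
        Q = np.eye(K)[labels]

    rng_g = substream(ext.seed, "genotypes")
    u = rng_g.random((n, 2, L, 1))
    cdf = np.cumsum(Q, axis=1)[:, None, None, :]
    src = (u > cdf).sum(axis=3)
    alleles = rng_g.random((n, 2, L)) < pop_freqs[src, np.arange(L)[None, None, :]]
    hap = alleles.reshape(2 * n, L).astype(np.int16)

    rng_m = substream(ext.seed, "mask")
    if ext.missing_rate > 0:
        mask = rng_m.random((2 * n, L)) < ext.missing_rate
        hap[mask] = MISSING

    gm = GenotypeMatrix(
        sample_ids=[f"S{labels[i]}_{i:03d}" for i in range(n)],
        haplotypes=hap,
        locus_of_site=[f"L{j}" for j in range(L)],
        populations=[f"pop{k}" for k in labels],
    )
    truth = SimTruth(true_label=labels, Q_true=Q, ancestral_freqs=anc, pop_freqs=pop_freqs)
    truth.validate()
    return gm, truth
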