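"""Diploid SNP genotype matrices in STRUCTURE text format.

The in-memory container is :class:`GenotypeMatrix`: an integer matrix with
two haplotype rows per individual (rows ``2i`` and ``2i+1`` belong to
sample *i*), allele states coded as small non-negative integers
(``0/1`` for biallelic data, ``0..3`` for nucleotide-coded data) and a
missing-data sentinel (``-9`` on disk). The operations here mirror the
matrix-construction conventions of RAD assembly pipelines: discarding
samples genotyped at too few loci, thinning to one randomly chosen SNP per
locus so sites can be treated as unlinked, and subsetting samples without
re-filtering sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from snpdelim._rng import substream

MISSING = -9
DEFAULT_MISSING_TOKEN = "-9"

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "MatrixSummary",
    "StructureParseError",
    "MalformedPairError",
    "EmptyMatrixError",
    "read_structure",
    "write_structure",
    "read_locus_map",
    "summarize",
    "filter_low_coverage_samples",
    "select_unlinked_snps",
    "subset_samples",
    "prune_uninformative_sites",
]


class StructureParseError(ValueError):
    """Raised when a STRUCTURE-format file cannot be parsed."""


class MalformedPairError(StructureParseError):
    """Raised when an individual's two haplotype rows are inconsistent."""


class EmptyMatrixError(ValueError):
    """Raised when an operation would leave no samples (or received none)."""


@dataclass
class GenotypeMatrix:
    """Haplotype-row diploid SNP matrix with a missing-data mask.

    Parameters
    ----------
    sample_ids
        Ordered individual identifiers; row ``2i``/``2i+1`` of
        ``haplotypes`` are the two allele copies of ``sample_ids[i]``.
    haplotypes
        ``(2*n_samples, n_sites)`` integer array; entries are allele codes
        ``>= 0`` or :data:`MISSING`.
    locus_of_site
        Optional per-site locus identifier (length ``n_sites``); required
        for unlinked-SNP thinning and locus-level coverage.
    populations
        Optional per-sample labels carried through from the file's
        population column.
    """

    sample_ids: list[str]
    haplotypes: np.ndarray
    locus_of_site: list | None = None
    populations: list | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int16)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2 * n:
            raise ValueError(
                f"haplotype row count {self.haplotypes.shape[0]} != 2 x {n} samples"
            )
        bad = (self.haplotypes < 0) & (self.haplotypes != MISSING)
        if bad.any():
            raise ValueError("entries must be allele codes >= 0 or the missing sentinel")
        if self.locus_of_site is not None and len(self.locus_of_site) != self.n_sites:
            raise ValueError("locus_of_site must name every site exactly once")
        if self.populations is not None and len(self.populations) != n:
            raise ValueError("populations must have one label per sample")

    # -- derived views --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(2n, n_sites)`` mask, True where the call is missing."""
        return self.haplotypes == MISSING

    @property
    def n_states(self) -> int:
        obs = self.haplotypes[~self.missing_mask]
        return int(obs.max()) + 1 if obs.size else 0

    @property
    def loci(self) -> list:
        """Locus identifiers in order of first appearance."""
        if self.locus_of_site is None:
            return list(range(self.n_sites))
        seen: dict = {}
        for lo in self.locus_of_site:
            seen.setdefault(lo, None)
        return list(seen)

    def hap_sample_map(self) -> np.ndarray:
        """Row index -> sample index (length ``2n``)."""
        return np.repeat(np.arange(self.n_samples), 2)

    def sample_locus_coverage(self) -> np.ndarray:
        """Per-sample fraction of loci with >= 1 called site (either copy)."""
        called = ~self.missing_mask
        per_sample_site = called[0::2] | called[1::2]  # (n, sites)
        if self.locus_of_site is None:
            return per_sample_site.mean(axis=1)
        loci = self.loci
        idx = {lo: i for i, lo in enumerate(loci)}
        col = np.array([idx[lo] for lo in self.locus_of_site])
        cov = np.zeros((self.n_samples, len(loci)), dtype=bool)
        for j in range(len(loci)):
            sites_j = col == j
            cov[:, j] = per_sample_site[:, sites_j].any(axis=1)
        return cov.mean(axis=1)


@dataclass
class MatrixSummary:
    n_samples: int
    n_loci: int
    n_sites: int
    pct_missing: float
    per_sample_coverage: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


# ---------------------------------------------------------------------------
# STRUCTURE text format
# ---------------------------------------------------------------------------

def _parse_allele(token: str, missing_token: str, row: int, col: int) -> int:
    if token == missing_token:
        return MISSING
    try:
        v = int(token)
    except ValueError:
        raise StructureParseError(
            f"unparseable allele token {token!r} at row {row}, column {col}"
        ) from None
    if v < 0:
        raise StructureParseError(
            f"negative allele code {v} at row {row}, column {col}"
        )
    return v


def read_structure(
    path: str | Path,
    allele_encoding: str = "auto",
    *,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    pop_column: bool | str = "auto",
    locus_of_site: Sequence | None = None,
) -> GenotypeMatrix:
    """Read a two-row-per-individual STRUCTURE matrix.

    Each non-blank line is ``sample_id [pop] allele allele ...``; ragged
    whitespace is tolerated. ``allele_encoding`` is ``"biallelic"`` (codes
    0/1), ``"nucleotide"`` (codes 0..3) or ``"auto"`` (any non-negative
    integers). ``pop_column="auto"`` treats the second column as a
    population label iff it is identical within every haplotype-row pair
    and contains some token that cannot be an allele code; purely numeric
    population labels are indistinguishable from a homozygous first site,
    so pass an explicit bool for such files.
    """
    lines = [
        (i + 1, ln.split())
        for i, ln in enumerate(Path(path).read_text().splitlines())
        if ln.strip()
    ]
    if not lines:
        raise EmptyMatrixError(f"{path}: no data rows")
    if len(lines) % 2:
        raise MalformedPairError(f"{path}: odd number of rows ({len(lines)})")

    pairs = []
    for a, b in zip(lines[0::2], lines[1::2]):
        (ra, ta), (rb, tb) = a, b
        if not ta or not tb or ta[0] != tb[0]:
            raise MalformedPairError(
                f"rows {ra} and {rb} do not form a haplotype pair "
                f"({ta[0] if ta else '?'} vs {tb[0] if tb else '?'})"
            )
        if len(ta) != len(tb):
            raise MalformedPairError(
                f"haplotype rows of {ta[0]!r} have different lengths "
                f"({len(ta) - 1} vs {len(tb) - 1} tokens)"
            )
        if len(ta) < 2:
            raise StructureParseError(f"row {ra}: no genotype tokens")
        pairs.append(((ra, ta), (rb, tb)))

    if pop_column == "auto":
        has_pop = _detect_pop_column(pairs, missing_token)
    else:
        has_pop = bool(pop_column)
    start = 2 if has_pop else 1

    sample_ids, populations, rows = [], [], []
    for (ra, ta), (rb, tb) in pairs:
        if len(ta) - start < 1:
            raise StructureParseError(f"row {ra}: no genotype tokens after metadata")
        sample_ids.append(ta[0])
        populations.append(ta[start - 1] if has_pop else None)
        for rown, toks in ((ra, ta), (rb, tb)):
            rows.append(
                [
                    _parse_allele(t, missing_token, rown, c + start)
                    for c, t in enumerate(toks[start:])
                ]
            )
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise MalformedPairError(f"{path}: inconsistent site counts {sorted(widths)}")

    hap = np.array(rows, dtype=np.int16)
    _check_encoding(hap, allele_encoding)
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        haplotypes=hap,
        locus_of_site=list(locus_of_site) if locus_of_site is not None else None,
        populations=populations if has_pop else None,
    )
    return gm


def _detect_pop_column(pairs, missing_token: str) -> bool:
    if any(len(ta) < 3 for (_, ta), _ in pairs):
        return False
    second = [(ta[1], tb[1]) for (_, ta), (_, tb) in pairs]
    if any(a != b for a, b in second):
        return False  # differs within a pair: must be a genotype site

    def invalid(tok: str) -> bool:
        if tok == missing_token:
            return False
        try:
            return int(tok) < 0
        except ValueError:
            return True

    # only a token that cannot be an allele proves a population column;
    # all-numeric labels are indistinguishable from a homozygous first
    # site, so auto stays conservative (pass pop_column=True to force)
    return any(invalid(a) for a, _ in second)


def _check_encoding(hap: np.ndarray, allele_encoding: str) -> None:
    limits = {"biallelic": 2, "nucleotide": 4, "auto": None}
    if allele_encoding not in limits:
        raise ValueError(f"unknown allele_encoding {allele_encoding!r}")
    lim = limits[allele_encoding]
    if lim is not None:
        obs = hap[hap != MISSING]
        if obs.size and obs.max() >= lim:
            raise StructureParseError(
                f"allele code {int(obs.max())} exceeds {allele_encoding} encoding"
            )


def write_structure(
    gm: GenotypeMatrix,
    path: str | Path,
    *,
    missing_token: str = DEFAULT_MISSING_TOKEN,
) -> None:
    """Write ``gm`` as whitespace-delimited STRUCTURE text (round-trip safe)."""
    out = []
    for i, sid in enumerate(gm.sample_ids):
        for h in (2 * i, 2 * i + 1):
            toks = [sid]
            if gm.populations is not None:
                toks.append(str(gm.populations[i]))
            toks.extend(
                missing_token if v == MISSING else str(int(v))
                for v in gm.haplotypes[h]
            )
            out.append(" ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


def read_locus_map(path: str | Path) -> list[str]:
    """One locus identifier per site, one per line (or whitespace-separated)."""
    return Path(path).read_text().split()


# ---------------------------------------------------------------------------
# Filtering / subsetting / summaries
# ---------------------------------------------------------------------------

def summarize(gm: GenotypeMatrix) -> MatrixSummary:
    """Counts and missingness of a matrix, on the haplotype-entry scale."""
    total = gm.haplotypes.size
    pct = 100.0 * gm.missing_mask.sum() / total if total else 0.0
    cov = gm.sample_locus_coverage()
    return MatrixSummary(
        n_samples=gm.n_samples,
        n_loci=len(gm.loci),
        n_sites=gm.n_sites,
        pct_missing=float(pct),
        per_sample_coverage={s: float(c) for s, c in zip(gm.sample_ids, cov)},
    )


def filter_low_coverage_samples(
    gm: GenotypeMatrix, min_fraction: float = 0.20
) -> tuple[GenotypeMatrix, list[str]]:
    """Drop samples genotyped at fewer than ``min_fraction`` of loci.

    The threshold is strict (coverage exactly at ``min_fraction`` is
    retained). Returns the filtered matrix and the removed sample ids.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    cov = gm.sample_locus_coverage()
    keep = cov >= min_fraction
    removed = [s for s, k in zip(gm.sample_ids, keep) if not k]
    if not keep.any():
        raise EmptyMatrixError("coverage filter removed every sample")
    if keep.all():
        return gm, []
    return subset_samples(gm, [s for s, k in zip(gm.sample_ids, keep) if k]), removed


def select_unlinked_snps(gm: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Keep one uniformly chosen SNP site per locus.

    Deterministic for a fixed seed; each locus draws from its own
    counter-based sub-stream (keyed by the locus's first-appearance index)
    so appending loci never changes earlier loci's choices.
    """
    if gm.locus_of_site is None:
        raise ValueError("select_unlinked_snps requires locus_of_site")
    loci = gm.loci
    site_idx = {lo: [] for lo in loci}
    for j, lo in enumerate(gm.locus_of_site):
        site_idx[lo].append(j)
    chosen = []
    for i, lo in enumerate(loci):
        sites = site_idx[lo]
        rng = substream(seed, "unlinked-snp", i)
        chosen.append(sites[int(rng.integers(len(sites)))])
    chosen = sorted(chosen)
    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        haplotypes=gm.haplotypes[:, chosen].copy(),
        locus_of_site=[gm.locus_of_site[j] for j in chosen],
        populations=list(gm.populations) if gm.populations is not None else None,
    )


def subset_samples(gm: GenotypeMatrix, ids: Iterable[str]) -> GenotypeMatrix:
    """Restrict to ``ids``, preserving original sample order and all sites.

    Sites are deliberately left untouched (no re-pruning of loci that
    become invariant or all-missing), so a subset is directly comparable
    to its parent matrix.
    """
    ids = list(ids)
    unknown = [s for s in ids if s not in set(gm.sample_ids)]
    if unknown:
        raise KeyError(f"unknown sample ids: {unknown}")
    if not ids:
        raise EmptyMatrixError("subset_samples received an empty id list")
    want = set(ids)
    keep = [i for i, s in enumerate(gm.sample_ids) if s in want]
    rows = np.concatenate([[2 * i, 2 * i + 1] for i in keep])
    return GenotypeMatrix(
        sample_ids=[gm.sample_ids[i] for i in keep],
        haplotypes=gm.haplotypes[rows].copy(),
        locus_of_site=list(gm.locus_of_site) if gm.locus_of_site is not None else None,
        populations=[gm.populations[i] for i in keep] if gm.populations is not None else None,
    )


def prune_uninformative_sites(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Optional post-hoc pruner: drop all-missing and invariant sites.

    Off by default everywhere; provided for users who do want a subset
    re-tightened.
    """
    obs = ~gm.missing_mask
    keep = []
    for j in range(gm.n_sites):
        vals = np.unique(gm.haplotypes[obs[:, j], j])
        if len(vals) >= 2:
            keep.append(j)
    if not keep:
        raise EmptyMatrixError("pruning removed every site")
    return GenotypeMatrix(
        sample_ids=list(gm.sample_ids),
        haplotypes=gm.haplotypes[:, keep].copy(),
        locus_of_site=[gm.locus_of_site[j] for j in keep]
        if gm.locus_of_site is not None
        else None,
        populations=list(gm.populations) if gm.populations is not None else None,
    )
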