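"""STRUCTURE-format I/O, filtering, thinning, subsetting."""

import numpy as np
import pytest

from snpdelim.genotypes import (
    MISSING,
    EmptyMatrixError,
    GenotypeMatrix,
    MalformedPairError,
    StructureParseError,
    filter_low_coverage_samples,
    read_structure,
    select_unlinked_snps,
    subset_samples,
    summarize,
    write_structure,
)
from tests.conftest import random_matrix


def write(tmp_path, text, name="m.str"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadStructure:
    def test_two_sample_three_site_with_one_missing(self, tmp_path):
        p = write(tmp_path, "A 0 1 1\nA 0 -9 1\nB 1 0 0\nB 1 1 0\n")
        gm = read_structure(p)
        assert gm.n_sites == 3
        assert gm.sample_ids == ["A", "B"]
        assert gm.missing_mask.sum() == 1
        assert gm.haplotypes[1, 1] == MISSING

    def test_ragged_whitespace_tolerated(self, tmp_path):
        p = write(tmp_path, "A  0   1 1\nA\t0 -9  1\nB 1 0 0\nB 1 1 0")
        assert read_structure(p).n_sites == 3

    def test_pair_rows_of_different_length_is_malformed(self, tmp_path):
        p = write(tmp_path, "P49 0 1 1\nP49 0 1\nB 1 0 0\nB 1 1 0\n")
        with pytest.raises(MalformedPairError, match="P49"):
            read_structure(p)

    def test_odd_row_count_is_malformed(self, tmp_path):
        p = write(tmp_path, "A 0 1\nA 0 1\nB 1 0\n")
        with pytest.raises(MalformedPairError):
            read_structure(p)

    def test_bad_token_names_row_and_column(self, tmp_path):
        p = write(tmp_path, "A 0 X 1\nA 0 1 1\nB 1 0 0\nB 1 1 0\n")
        with pytest.raises(StructureParseError, match=r"row 1.*column 2"):
            read_structure(p, pop_column=False)

    def test_population_column_detected(self, tmp_path):
        p = write(tmp_path, "A north 0 1\nA north 0 0\nB south 1 0\nB south 1 0\n")
        gm = read_structure(p)
        assert gm.populations == ["north", "south"]
        assert gm.n_sites == 2

    @pytest.mark.parametrize("with_pop", [False, True])
    def test_write_read_round_trip_is_byte_identical(self, tmp_path, with_pop):
        rng = np.random.default_rng(5)
        for trial in range(20):
            gm = random_matrix(rng, n=rng.integers(2, 6), sites=rng.integers(2, 9),
                               with_pop=with_pop)
            p = tmp_path / f"rt{with_pop}_{trial}.str"
            write_structure(gm, p)
            gm2 = read_structure(p, pop_column=with_pop)
            write_structure(gm2, tmp_path / "again.str")
            assert (tmp_path / "again.str").read_bytes() == p.read_bytes()
            assert np.array_equal(gm.haplotypes, gm2.haplotypes)


try:
    from hypothesis import given, settings, strategies as st

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        n=st.integers(1, 5),
        sites=st.integers(1, 8),
        data=st.data(),
    )
    def test_round_trip_property(tmp_path_factory, n, sites, data):
        """write -> read is lossless for any matrix the generator can emit."""
        cells = data.draw(
            st.lists(
                st.integers(-1, 3).map(lambda v: MISSING if v == -1 else v),
                min_size=2 * n * sites, max_size=2 * n * sites,
            )
        )
        gm = GenotypeMatrix(
            sample_ids=[f"S{i}" for i in range(n)],
            haplotypes=np.array(cells, dtype=np.int16).reshape(2 * n, sites),
        )
        p = tmp_path_factory.mktemp("rt") / "m.str"
        write_structure(gm, p)
        gm2 = read_structure(p, pop_column=False)
        assert np.array_equal(gm.haplotypes, gm2.haplotypes)
        assert gm2.sample_ids == gm.sample_ids
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


class TestSummarize:
    def test_percent_missing_arithmetic(self):
        hap = np.zeros((4, 5), dtype=np.int16)
        hap[0, :2] = MISSING
        hap[2, :2] = MISSING
        gm = GenotypeMatrix(sample_ids=["a", "b"], haplotypes=hap)
        assert summarize(gm).pct_missing == pytest.approx(20.0)

    def test_fully_observed_is_zero(self):
        gm = GenotypeMatrix(sample_ids=["a"], haplotypes=np.ones((2, 4), dtype=np.int16))
        assert summarize(gm).pct_missing == 0.0

    def test_counts(self, tiny_matrix):
        s = summarize(tiny_matrix)
        assert (s.n_samples, s.n_loci, s.n_sites) == (2, 2, 3)


class TestCoverageFilter:
    @staticmethod
    def _gm_with_coverage(frac: float, n_loci: int = 100) -> GenotypeMatrix:
        hap = np.full((4, n_loci), MISSING, dtype=np.int16)
        hap[0:2] = 0  # first sample fully covered
        k = int(round(frac * n_loci))
        hap[2, :k] = 1  # second sample: k loci called on one haplotype
        return GenotypeMatrix(sample_ids=["good", "low"], haplotypes=hap,
                              locus_of_site=[f"L{j}" for j in range(n_loci)])

    def test_below_threshold_removed(self):
        gm, removed = filter_low_coverage_samples(self._gm_with_coverage(0.19), 0.20)
        assert removed == ["low"]
        assert gm.sample_ids == ["good"]

    def test_exactly_at_threshold_retained(self):
        gm, removed = filter_low_coverage_samples(self._gm_with_coverage(0.20), 0.20)
        assert removed == []

    def test_zero_threshold_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            filter_low_coverage_samples(tiny_matrix, 0.0)

    def test_removing_everything_raises(self):
        hap = np.full((2, 10), MISSING, dtype=np.int16)
        hap[0, 0] = 0
        gm = GenotypeMatrix(sample_ids=["only"], haplotypes=hap)
        with pytest.raises(EmptyMatrixError):
            filter_low_coverage_samples(gm, 0.5)

    def test_filtering_never_alters_retained_entries(self):
        rng = np.random.default_rng(0)
        gm = random_matrix(rng, n=6, sites=8)
        out, removed = filter_low_coverage_samples(gm, 0.2)
        assert out.n_samples + len(removed) == gm.n_samples
        for i, sid in enumerate(out.sample_ids):
            j = gm.sample_ids.index(sid)
            assert np.array_equal(out.haplotypes[2 * i:2 * i + 2],
                                  gm.haplotypes[2 * j:2 * j + 2])


class TestUnlinkedSnps:
    def _gm(self):
        # loci with 2, 1, 4 SNP sites
        loci = ["a", "a", "b", "c", "c", "c", "c"]
        hap = np.tile(np.arange(7, dtype=np.int16), (4, 1))  # unique columns
        return GenotypeMatrix(sample_ids=["x", "y"], haplotypes=hap, locus_of_site=loci)

    def test_one_site_per_locus(self):
        out = select_unlinked_snps(self._gm(), seed=1)
        assert out.n_sites == 3
        assert out.locus_of_site == ["a", "b", "c"]

    def test_deterministic_for_fixed_seed(self):
        a = select_unlinked_snps(self._gm(), seed=7)
        b = select_unlinked_snps(self._gm(), seed=7)
        assert np.array_equal(a.haplotypes, b.haplotypes)

    def test_retained_columns_are_input_columns(self):
        gm = self._gm()
        out = select_unlinked_snps(gm, seed=3)
        cols = {tuple(gm.haplotypes[:, j]) for j in range(gm.n_sites)}
        for j in range(out.n_sites):
            assert tuple(out.haplotypes[:, j]) in cols

    def test_per_locus_choice_is_uniform(self):
        # the 4-site locus: each site picked with freq 0.25 +/- 0.02
        gm = self._gm()
        counts = np.zeros(4)
        for seed in range(10_000):
            out = select_unlinked_snps(gm, seed=seed)
            picked = out.haplotypes[:, 2]
            for j in range(3, 7):
                if np.array_equal(picked, gm.haplotypes[:, j]):
                    counts[j - 3] += 1
                    break
        freqs = counts / 10_000
        assert np.all(np.abs(freqs - 0.25) < 0.02)

    def test_counter_substream_stable_under_added_loci(self):
        gm = self._gm()
        ext = GenotypeMatrix(
            sample_ids=gm.sample_ids,
            haplotypes=np.hstack([gm.haplotypes, gm.haplotypes[:, :2]]),
            locus_of_site=gm.locus_of_site + ["d", "d"],
        )
        a = select_unlinked_snps(gm, seed=9)
        b = select_unlinked_snps(ext, seed=9)
        assert np.array_equal(a.haplotypes, b.haplotypes[:, :3])

    def test_missing_locus_map_raises(self, tiny_matrix):
        tiny_matrix.locus_of_site = None
        with pytest.raises(ValueError):
            select_unlinked_snps(tiny_matrix, seed=0)


class TestSubsetSamples:
    def test_identity(self, tiny_matrix):
        out = subset_samples(tiny_matrix, tiny_matrix.sample_ids)
        assert np.array_equal(out.haplotypes, tiny_matrix.haplotypes)

    def test_row_count_after_subset(self):
        rng = np.random.default_rng(2)
        gm = random_matrix(rng, n=35, sites=5)
        out = subset_samples(gm, gm.sample_ids[:27])
        assert out.n_haplotypes == 54
        assert out.n_sites == gm.n_sites  # sites never re-pruned

    def test_empty_subset_raises(self, tiny_matrix):
        with pytest.raises(EmptyMatrixError):
            subset_samples(tiny_matrix, [])

    def test_unknown_id_listed(self, tiny_matrix):
        with pytest.raises(KeyError, match="nope"):
            subset_samples(tiny_matrix, ["P1", "nope"])

    def test_subset_then_thinning_keeps_same_loci(self):
        # removing samples and rerunning never changes the chosen sites
        rng = np.random.default_rng(3)
        gm = random_matrix(rng, n=8, sites=10)
        a = select_unlinked_snps(gm, seed=4)
        b = select_unlinked_snps(subset_samples(gm, gm.sample_ids[:5]), seed=4)
        assert a.locus_of_site == b.locus_of_site
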