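"""SFS construction, p_lth scaling, file dialect round-trips, dispersion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gammalethal.sfs import (SFS, SFSDataset, SFSParseError, build_unfolded_sfs,
                             read_dataset, scale_sfs, sfs_dispersion,
                             sfs_from_derived_counts, write_dataset)


def brute_force_sfs(haplotypes, n):
    """Independent oracle: tabulate carrier counts with a plain dict."""
    carriers = {}
    for hap in haplotypes:
        for pos in hap:
            carriers[pos] = carriers.get(pos, 0) + 1
    counts = [0] * (n - 1)
    for c in carriers.values():
        if 1 <= c <= n - 1:
            counts[c - 1] += 1
    return np.asarray(counts, dtype=float)


class TestBuildUnfoldedSFS:
    def test_no_segregating_sites(self):
        sfs = build_unfolded_sfs([np.empty(0)] * 4, 4)
        assert np.all(sfs.counts == 0)

    def test_toy_example(self):
        # one singleton site; two sites carried by 3 of 4 haplotypes
        haps = [np.array([0.1, 0.5, 0.9]), np.array([0.5, 0.9]),
                np.array([0.5, 0.9]), np.empty(0)]
        sfs = build_unfolded_sfs(haps, 4)
        np.testing.assert_array_equal(sfs.counts, [1.0, 0.0, 2.0])

    def test_fixed_sites_excluded_and_sum_conserved(self):
        shared = np.array([0.42])
        haps = [np.sort(np.r_[shared, np.random.default_rng(i).uniform(size=3)])
                for i in range(4)]
        sfs = build_unfolded_sfs(haps, 4)
        oracle = brute_force_sfs([list(h) for h in haps], 4)
        np.testing.assert_array_equal(sfs.counts, oracle)
        # 0.42 is fixed in the sample and must not be counted
        total_sites = len({p for h in haps for p in h})
        assert sfs.counts.sum() == total_sites - 1

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.lists(st.integers(0, 30), max_size=15),
                    min_size=2, max_size=8))
    def test_matches_brute_force_oracle(self, int_haps):
        n = len(int_haps)
        haps = [np.unique(np.asarray(h, dtype=float)) for h in int_haps]
        sfs = build_unfolded_sfs(haps, n)
        np.testing.assert_array_equal(
            sfs.counts, brute_force_sfs([list(h) for h in haps], n))

    def test_wrong_sample_size_rejected(self):
        with pytest.raises(ValueError):
            build_unfolded_sfs([np.empty(0)] * 3, 4)


class TestScaleSFS:
    def test_endpoints_and_arithmetic(self):
        sfs = SFS(np.array([10.0, 5.0, 2.0]), n=4, kind="selected")
        assert np.array_equal(scale_sfs(sfs, 0.0).counts, sfs.counts)
        assert np.all(scale_sfs(sfs, 1.0).counts == 0)
        np.testing.assert_allclose(scale_sfs(sfs, 0.3).counts, [7.0, 3.5, 1.4])

    def test_neutral_never_scaled_and_range_checked(self):
        neutral = SFS(np.array([1.0, 1.0, 1.0]), n=4, kind="neutral")
        with pytest.raises(ValueError):
            scale_sfs(neutral, 0.5)
        sel = SFS(np.array([1.0, 1.0, 1.0]), n=4, kind="selected")
        with pytest.raises(ValueError):
            scale_sfs(sel, 1.5)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.0, 1.0))
    def test_scaling_commutes_with_averaging(self, p):
        a = SFS(np.array([4.0, 2.0, 1.0]), n=4, kind="selected")
        b = SFS(np.array([8.0, 0.0, 3.0]), n=4, kind="selected")
        avg_then_scale = scale_sfs(
            SFS((a.counts + b.counts) / 2, n=4, kind="selected"), p).counts
        scale_then_avg = (scale_sfs(a, p).counts + scale_sfs(b, p).counts) / 2
        np.testing.assert_allclose(avg_then_scale, scale_then_avg)


class TestDatasetIO:
    def _dataset(self, n=20, pairs=2, species=None, seed=0):
        rng = np.random.default_rng(seed)
        mk = lambda kind: SFS(rng.integers(0, 50, n - 1).astype(float) + 0.25,
                              n=n, kind=kind)
        return SFSDataset([(mk("neutral"), mk("selected"))
                           for _ in range(pairs)],
                          species or ["species_1"] * pairs)

    def test_round_trip_identity(self, tmp_path):
        ds = self._dataset()
        path = tmp_path / "pairs.sfs"
        write_dataset(ds, path)
        back = read_dataset(path)
        assert back.n == ds.n
        for (n1, s1), (n2, s2) in zip(ds.pairs, back.pairs):
            np.testing.assert_allclose(n1.counts, n2.counts)
            np.testing.assert_allclose(s1.counts, s2.counts)
            assert s1.length == s2.length

    def test_single_species_header(self, tmp_path):
        ds = self._dataset(pairs=50)
        path = tmp_path / "single.sfs"
        write_dataset(ds, path)
        header = path.read_text().splitlines()[1]
        assert header == "50 50 20"

    def test_multi_species_blocks(self, tmp_path):
        ds = self._dataset(pairs=60, species=["lyrata"] * 20
                           + ["grandiflora"] * 20 + ["mays"] * 20)
        path = tmp_path / "trio.sfs"
        write_dataset(ds, path)
        headers = [l for l in path.read_text().splitlines()
                   if l and not l.startswith("#")
                   and len(l.split()) == 3 and "." not in l]
        assert headers == ["20 20 20"] * 3
        back = read_dataset(path)
        assert back.species_names() == ["lyrata", "grandiflora", "mays"]
        assert len(back.pairs) == 60

    def test_parse_error_reports_line(self, tmp_path):
        path = tmp_path / "bad.sfs"
        path.write_text("1 1 4\n1 2 3 20000\n1 2 nope 20000\n")
        with pytest.raises(SFSParseError) as err:
            read_dataset(path)
        assert err.value.lineno == 3

    def test_from_derived_counts(self):
        sfs = sfs_from_derived_counts([1, 1, 3, 4, 0], n=4, kind="selected")
        np.testing.assert_array_equal(sfs.counts, [2.0, 0.0, 1.0])


class TestDispersion:
    def _ds(self, counts):
        n = len(counts) + 1
        return SFSDataset([(SFS(np.ones(n - 1), n=n),
                            SFS(np.asarray(counts, float), n=n,
                                kind="selected"))])

    def test_identical_datasets_have_zero_dispersion(self):
        d = self._ds([5.0, 2.0, 1.0])
        disp = sfs_dispersion([d, d, d])
        assert np.all(disp["sd"] == 0)

    def test_dispersion_scales_exactly_with_one_minus_plth(self):
        base = [self._ds([5.0, 2.0, 1.0]), self._ds([9.0, 1.0, 4.0]),
                self._ds([2.0, 7.0, 0.5])]
        sd0 = sfs_dispersion(base)["sd"].to_numpy()
        for p in (0.3, 0.9):
            scaled = [
                SFSDataset([(neu, scale_sfs(sel, p)) for neu, sel in d.pairs])
                for d in base
            ]
            np.testing.assert_allclose(sfs_dispersion(scaled)["sd"],
                                       (1 - p) * sd0)

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError):
            sfs_dispersion([self._ds([1.0, 2.0, 3.0]),
                            self._ds([1.0, 2.0, 3.0, 4.0])])
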