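import numpy as np
import pytest

from epinet import (
    BinnedStore,
    CoverageRecord,
    CpGRecord,
    FeatureTrack,
    GenomeAssembly,
    MethylationTrack,
    assemble_matrix,
    bin_methylation,
    compute_fpkm,
    make_bins,
    neighbor_mean,
    scale_feature,
    scale_methylation,
)


class TestMakeBins:
    @pytest.mark.parametrize(
        "length,bin_size,n_bins,last",
        [(2500, 1000, 3, (2000, 2500)), (1000, 1000, 1, (0, 1000)),
         (999, 1000, 1, (0, 999))],
    )
    def test_tiling(self, length, bin_size, n_bins, last):
        bins = make_bins(GenomeAssembly(("c",), (length,)), bin_size)
        assert bins.n_bins == n_bins
        assert bins.coords(n_bins - 1) == ("c", *last)

    def test_bins_tile_without_gaps(self, tiny_bins):
        for chrom in tiny_bins.assembly.chrom_names:
            sl = tiny_bins.chrom_slice(chrom)
            starts, ends = tiny_bins.starts[sl], tiny_bins.ends[sl]
            assert starts[0] == 0
            assert np.array_equal(starts[1:], ends[:-1])
            assert ends[-1] == tiny_bins.assembly.length_of(chrom)

    def test_invalid_bin_size(self, tiny_assembly):
        with pytest.raises(ValueError):
            make_bins(tiny_assembly, 0)


def _brute_force_bin_methylation(cpgs, bins, min_depth=5, max_depth=100, min_sites=5):
    """Independent per-site loop oracle."""
    per_bin = {}
    for rec in cpgs:
        cov = rec.meth_reads + rec.unmeth_reads
        if not (min_depth <= cov <= max_depth):
            continue
        b = bins.bin_of(rec.chrom, rec.pos - 1)
        per_bin.setdefault(b, []).append(rec.meth_reads / cov)
    level = np.full(bins.n_bins, np.nan)
    for b, fractions in per_bin.items():
        if len(fractions) >= min_sites:
            level[b] = sum(fractions) / len(fractions)
    return level


class TestBinMethylation:
    def test_five_identical_sites(self, tiny_bins):
        cpgs = [CpGRecord("chrT", 100 + i, 8, 2) for i in range(5)]
        track = bin_methylation(cpgs, tiny_bins)
        assert track.level[0] == pytest.approx(0.8)
        assert track.n_informative[0] == 5

    def test_four_informative_sites_excluded(self, tiny_bins):
        cpgs = [CpGRecord("chrT", 100 + i, 8, 2) for i in range(4)]
        track = bin_methylation(cpgs, tiny_bins)
        assert np.isnan(track.level[0])
        assert track.n_informative[0] == 4

    @pytest.mark.parametrize(
        "coverage,informative",
        [(4, False), (5, True), (100, True), (101, False)],
    )
    def test_depth_filter_inclusive_bounds(self, tiny_bins, coverage, informative):
        meth = coverage // 2
        cpgs = [CpGRecord("chrT", 100 + i, meth, coverage - meth) for i in range(5)]
        track = bin_methylation(cpgs, tiny_bins)
        assert bool(track.n_informative[0] == 5) is informative

    def test_matches_brute_force_oracle(self, tiny_bins, rng):
        cpgs = []
        for chrom, length in zip(tiny_bins.assembly.chrom_names,
                                 tiny_bins.assembly.chrom_lengths):
            positions = np.unique(rng.integers(1, length + 1, size=400))
            for pos in positions:
                cov = int(rng.integers(0, 130))
                meth = int(rng.integers(0, cov + 1)) if cov else 0
                cpgs.append(CpGRecord(chrom, int(pos), meth, cov - meth))
        got = bin_methylation(cpgs, tiny_bins).level
        expected = _brute_force_bin_methylation(cpgs, tiny_bins)
        np.testing.assert_array_equal(np.isnan(got), np.isnan(expected))
        np.testing.assert_allclose(got[~np.isnan(got)], expected[~np.isnan(expected)])

    def test_empty_input_all_missing(self, tiny_bins):
        track = bin_methylation([], tiny_bins)
        assert np.isnan(track.level).all()

    def test_pooled_counts_mode_weights_by_coverage(self, tiny_bins):
        cpgs = [CpGRecord("chrT", 100 + i, 10, 0) for i in range(4)]
        cpgs.append(CpGRecord("chrT", 104, 0, 40))
        site_mean = bin_methylation(cpgs, tiny_bins).level[0]
        pooled = bin_methylation(cpgs, tiny_bins, pool_counts=True).level[0]
        assert site_mean == pytest.approx(0.8)
        assert pooled == pytest.approx(40 / 80)


class TestComputeFpkm:
    def test_ten_fragments_in_one_kb_bin(self, tiny_bins):
        records = [CoverageRecord("chrT", 100, 200, 10.0)]
        track = compute_fpkm(records, tiny_bins, 10_000_000)
        assert track.values[0] == pytest.approx(1.0)

    def test_no_fragments_zero(self, tiny_bins):
        assert compute_fpkm([], tiny_bins, 1e6).values.sum() == 0.0

    def test_boundary_fragment_split_half_and_half(self, tiny_bins):
        records = [CoverageRecord("chrT", 900, 1100, 1.0)]
        track = compute_fpkm(records, tiny_bins, 1e6)
        # overlap-fraction rule: 100 bp in each bin -> 0.5 fragments each
        assert track.values[0] == pytest.approx(0.5)
        assert track.values[1] == pytest.approx(0.5)

    def test_overlap_weights_match_bp_level_count(self, tiny_bins, rng):
        # brute force: spread each fragment's mass uniformly over its bases
        records = []
        for _ in range(50):
            start = int(rng.integers(0, 4500))
            end = int(rng.integers(start + 1, min(start + 800, 5000) + 1))
            records.append(CoverageRecord("chrT", start, end, float(rng.integers(1, 5))))
        got = compute_fpkm(records, tiny_bins, 1e6).values
        bp_mass = np.zeros(5000)
        for rec in records:
            bp_mass[rec.start:rec.end] += rec.value / (rec.end - rec.start)
        sl = tiny_bins.chrom_slice("chrT")
        for i, b in enumerate(range(sl.start, sl.stop)):
            s, e = tiny_bins.starts[b], tiny_bins.ends[b]
            expected = bp_mass[s:e].sum() / ((e - s) / 1000) / 1.0
            assert got[b] == pytest.approx(expected, abs=1e-9)

    def test_mass_conservation(self, tiny_bins, rng):
        records = [
            CoverageRecord("chrU", int(s), int(s) + 250, 2.0)
            for s in rng.integers(0, 2750, size=30)
        ]
        track = compute_fpkm(records, tiny_bins, 5e6)
        bin_kb = (tiny_bins.ends - tiny_bins.starts) / 1000
        total = float(np.sum(track.values * bin_kb * 5.0))
        assert total == pytest.approx(sum(r.value for r in records), abs=1e-9)

    def test_nonpositive_total_raises(self, tiny_bins):
        with pytest.raises(ValueError):
            compute_fpkm([], tiny_bins, 0)


class TestScaleMethylation:
    @pytest.mark.parametrize("raw,expected", [(100, 1.0), (0, 0.0), (37.5, 0.375)])
    def test_percent_to_fraction(self, raw, expected):
        assert scale_methylation(raw) == pytest.approx(expected)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            scale_methylation(101.0)


class TestScaleFeature:
    def test_anchor_value_maps_to_095(self, rng):
        values = rng.gamma(2.0, 1.0, size=2000)
        scaled, anchor = scale_feature(FeatureTrack("f", values))
        assert anchor == pytest.approx(np.percentile(values, 95))
        assert np.percentile(scaled.values, 95) == pytest.approx(0.95, abs=1e-9)
        assert scaled.values.min() >= 0 and scaled.values.max() <= 1

    def test_zero_maps_to_zero_and_2p_clips(self):
        values = np.concatenate([np.linspace(0, 10, 100), [0.0]])
        scaled, p = scale_feature(FeatureTrack("f", values))
        assert scaled.values[-1] == 0.0
        over, _ = scale_feature(FeatureTrack("f", np.append(values, 2 * p)))
        assert over.values[-1] == 1.0

    def test_all_zero_track(self):
        scaled, _ = scale_feature(FeatureTrack("f", np.zeros(10)))
        assert (scaled.values == 0).all()

    def test_idempotent_scaling_stays_in_unit_interval(self, rng):
        track = FeatureTrack("f", rng.exponential(3.0, size=1000))
        once, _ = scale_feature(track)
        twice, _ = scale_feature(once)
        assert np.percentile(twice.values, 95) <= 0.95 + 1e-12
        assert twice.values.min() >= 0 and twice.values.max() <= 1


def _brute_force_neighbor_mean(values, bins, n_up=5, n_down=5):
    out = np.empty_like(values, dtype=float)
    for ci, chrom in enumerate(bins.assembly.chrom_names):
        sl = bins.chrom_slice(chrom)
        v = values[sl]
        for i in range(len(v)):
            window = [v[j] for j in range(max(0, i - n_up), min(len(v), i + n_down + 1))
                      if j != i]
            out[sl.start + i] = sum(window) / len(window) if window else v[i]
    return out


class TestNeighborMean:
    def test_constant_track(self, tiny_bins):
        values = np.full(tiny_bins.n_bins, 3.3)
        np.testing.assert_allclose(neighbor_mean(values, tiny_bins), 3.3)

    def test_interior_bin_hand_value(self):
        bins = make_bins(GenomeAssembly(("c",), (11_000,)), 1000)
        values = np.array([1, 1, 1, 1, 1, 99, 3, 3, 3, 3, 3], dtype=float)
        assert neighbor_mean(values, bins)[5] == pytest.approx(2.0)

    def test_first_bin_uses_downstream_only(self, tiny_bins, rng):
        values = rng.random(tiny_bins.n_bins)
        got = neighbor_mean(values, tiny_bins)
        # chrT has only 5 bins, so the first bin sees 4 downstream neighbors
        assert got[0] == pytest.approx(values[1:5].mean())

    def test_matches_window_enumeration_oracle(self, tiny_bins, rng):
        values = rng.random(tiny_bins.n_bins)
        np.testing.assert_allclose(
            neighbor_mean(values, tiny_bins),
            _brute_force_neighbor_mean(values, tiny_bins),
        )

    def test_single_bin_chromosome_falls_back_to_own_value(self):
        bins = make_bins(GenomeAssembly(("a", "b"), (500, 5000)), 1000)
        values = np.arange(bins.n_bins, dtype=float)
        got = neighbor_mean(values, bins)
        assert got[0] == values[0]

    def test_never_crosses_chromosomes(self, tiny_bins):
        values = np.zeros(tiny_bins.n_bins)
        values[tiny_bins.chrom_slice("chrU")] = 100.0
        got = neighbor_mean(values, tiny_bins)
        assert (got[tiny_bins.chrom_slice("chrT")] == 0).all()
        assert (got[tiny_bins.chrom_slice("chrU")] == 100).all()


class TestAssembleMatrix:
    def _meth(self, bins, valid_value=0.5):
        level = np.full(bins.n_bins, valid_value)
        level[1] = np.nan
        n_inf = np.where(np.isnan(level), 0, 7)
        return MethylationTrack(level, n_inf)

    def test_shape_and_invalid_bins(self, tiny_bins, rng):
        tracks = [FeatureTrack(n, rng.random(tiny_bins.n_bins)) for n in "ab"]
        matrix, targets = assemble_matrix(tracks, self._meth(tiny_bins), tiny_bins)
        assert matrix.data.shape == (tiny_bins.n_bins, 2, 2)
        assert not matrix.valid[1] and matrix.valid[0]
        assert np.isnan(targets[1])

    def test_neighbor_column_recomputable_from_own_column(self, tiny_bins, rng):
        tracks = [FeatureTrack("a", rng.random(tiny_bins.n_bins))]
        matrix, _ = assemble_matrix(tracks, self._meth(tiny_bins), tiny_bins)
        np.testing.assert_allclose(
            matrix.data[:, 0, 1], neighbor_mean(matrix.data[:, 0, 0], tiny_bins)
        )

    def test_subset_selection(self, tiny_bins, rng):
        tracks = [FeatureTrack(n, rng.random(tiny_bins.n_bins)) for n in "abc"]
        matrix, _ = assemble_matrix(tracks, self._meth(tiny_bins), tiny_bins)
        sub = matrix.subset(["b"])
        assert sub.data.shape[1] == 1
        np.testing.assert_array_equal(sub.data[:, 0, :], matrix.data[:, 1, :])

    def test_mismatched_bins_raise(self, tiny_bins):
        with pytest.raises(ValueError):
            assemble_matrix(
                [FeatureTrack("a", np.zeros(3))], self._meth(tiny_bins), tiny_bins
            )


def test_store_tsv_round_trip(tmp_path, tiny_bins, rng):
    store = BinnedStore(bins=tiny_bins)
    store.features["h3k36me3"] = FeatureTrack("h3k36me3", rng.random(tiny_bins.n_bins))
    level = rng.random(tiny_bins.n_bins)
    level[::3] = np.nan
    store.methylation = MethylationTrack(level, np.where(np.isnan(level), 0, 6))
    path = tmp_path / "store.tsv"
    store.to_tsv(path)
    loaded = BinnedStore.from_tsv(path, tiny_bins)
    np.testing.assert_allclose(
        loaded.features["h3k36me3"].values, store.features["h3k36me3"].values,
        rtol=1e-6,
    )
    np.testing.assert_array_equal(np.isnan(loaded.methylation.level), np.isnan(level))
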