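"""Layout descriptor: closed-form cases, brute-force oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from figcat import fixtures
from figcat.layout_features import (
    BLOCK_SLICES,
    FEATURE_DIM,
    FeatureVector,
    entropy_histograms,
    extract_features,
    fourier_structure,
    neighbor_distance_features,
    region_distance,
    regions_mask,
    regularity,
    scanline_entropy,
    scanline_profile,
    structure_histograms,
)
from figcat.textmap import TextRegion


def profile_of(bits, min_run=5):
    return scanline_profile(np.array(bits, dtype=bool), min_run=min_run)


class TestScanlineProfile:
    def test_noise_runs_discarded(self):
        line = [0] * 3 + [1] * 4 + [0] * 2 + [1] * 6 + [0] * 3 + [1] * 7 + [0] * 2
        p = profile_of(line)
        assert [l for _, l in p.runs] == [6, 7]  # the 4-run is noise
        assert p.gaps == [3]
        assert p.n_p == 17

    def test_gap_count_is_runs_minus_one(self):
        line = [1] * 5 + [0] * 4 + [1] * 5 + [0] * 2 + [1] * 8
        p = profile_of(line)
        assert len(p.gaps) == len(p.runs) - 1 == 2
        assert p.gaps == [4, 2]


class TestScanlineEntropy:
    def test_empty_and_single_run_zero(self):
        assert scanline_entropy(profile_of([0] * 10)) == 0.0
        assert scanline_entropy(profile_of([1] * 10)) == 0.0

    def test_two_equal_runs_one_bit(self):
        p = profile_of([1] * 6 + [0] * 5 + [1] * 6)
        assert scanline_entropy(p) == pytest.approx(1.0)

    def test_unequal_runs_closed_form(self):
        # runs 5 and 15: H = -(1/4 log2 1/4 + 3/4 log2 3/4)
        p = profile_of([1] * 5 + [0] * 6 + [1] * 15)
        expect = -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
        assert scanline_entropy(p) == pytest.approx(expect)


class TestEntropyHistograms:
    def test_blank_image_mass_in_bin_zero(self):
        h = entropy_histograms(np.zeros((12, 12), bool))
        assert h[:10].tolist() == [1] + [0] * 9
        assert h[10:].tolist() == [1] + [0] * 9

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_bruteforce_binning(self, seed):
        mask = np.random.default_rng(seed).random((20, 24)) < 0.45
        h = entropy_histograms(mask)
        for block, lines in ((h[:10], mask), (h[10:], mask.T)):
            ents = [scanline_entropy(profile_of(l)) for l in lines]
            hi = max(ents)
            expect = np.zeros(10)
            if hi == 0:
                expect[0] = 1.0
            else:
                for e in ents:
                    expect[min(int(e / hi * 10), 9)] += 1 / len(ents)
            assert block == pytest.approx(expect)
            assert block.sum() == pytest.approx(1.0)


class TestFourierStructure:
    def test_blank_lines_all_zero(self):
        assert fourier_structure(np.zeros((16, 16), bool)).tolist() == [0.0] * 40

    def test_quartile_order_on_fixture(self, table_figure):
        mask = regions_mask(table_figure.image.shape, table_figure.regions)
        v = fourier_structure(mask)
        for q in v.reshape(10, 4):
            lq, mean, med, hq = q
            assert lq <= med <= hq
            assert mean >= 0

    def test_square_wave_concentrates_at_coefficient_two(self):
        # vertical stripes of period W/2: every row is a square wave whose
        # energy (DC aside) sits at coefficient 2 of the length-W transform
        W = 64
        row = np.zeros(W)
        row[:16] = 1
        row[32:48] = 1
        mask = np.tile(row, (8, 1)).astype(bool)
        v = fourier_structure(mask)
        h = v[:20].reshape(5, 4)
        mags_by_j = h[:, 1]  # per-coefficient mean over identical rows
        expect_c2 = abs(np.fft.rfft(row)[2]) / W
        assert mags_by_j[1] == pytest.approx(expect_c2)
        assert mags_by_j[1] > 5 * max(mags_by_j[0], mags_by_j[2], mags_by_j[3])


class TestRegularity:
    @pytest.mark.parametrize(
        "gaps, tau, expect",
        [
            ([10, 10, 10], 3.0, 1.0),
            ([5, 50], 3.0, 0.5),
            ([8, 9, 10, 40], 3.0, 0.75),  # {8,9,10} merge, 40 stays out
            ([7], 3.0, 0.0),  # fewer than 2 gaps
            ([], 3.0, 0.0),
        ],
    )
    def test_hand_run_merges(self, gaps, tau, expect):
        p = scanline_profile(np.zeros(4, bool))
        p.gaps = list(gaps)
        assert regularity(p, tau) == pytest.approx(expect)

    def test_tau_must_be_positive(self):
        with pytest.raises(ValueError):
            regularity(scanline_profile(np.zeros(4, bool)), 0.0)


class TestStructureHistograms:
    def test_blank_image_degenerate(self):
        h = structure_histograms(np.zeros((12, 12), bool))
        assert h[:10].tolist() == [1] + [0] * 9
        assert h.sum() == pytest.approx(2.0)

    def test_table_more_regular_than_spot_chart(self):
        table = fixtures.generate_figure("table", seed=2)
        spot = fixtures.generate_figure("spot chart", seed=2)
        centers = (np.arange(10) + 0.5) / 10

        def mean_regularity(fig):
            m = regions_mask(fig.image.shape, fig.regions)
            return float(structure_histograms(m)[:10] @ centers)

        assert mean_regularity(table) > mean_regularity(spot)


class TestRegionDistance:
    def test_identical_rectangles_zero(self):
        r = TextRegion(3, 3, 9, 9)
        assert region_distance(r, r) == 0.0

    def test_horizontal_gap(self):
        a = TextRegion(0, 0, 1, 1)
        b = TextRegion(4, 0, 5, 1)  # x-gap 3, y-ranges overlap
        assert region_distance(a, b) == 3.0

    def test_diagonal_gap_pythagoras(self):
        a = TextRegion(0, 0, 2, 2)
        b = TextRegion(5, 6, 8, 9)  # gaps (3, 4)
        assert region_distance(a, b) == 5.0


def brute_force_distance_block(regions):
    """Independent re-derivation of the 20-dim distance block."""
    n = len(regions)
    if n < 2:
        return np.zeros(20)
    d = {
        (i, j): region_distance(regions[i], regions[j])
        for i in range(n)
        for j in range(n)
        if i != j
    }
    d_max = max(d.values())
    if d_max == 0:
        return np.zeros(20)
    k = max(1, n // 3)
    hists = []
    for i in range(n):
        nearest = sorted(d[i, j] for j in range(n) if j != i)[:k]
        h = [0.0] * 5
        for v in nearest:
            h[min(int(v * 5 / d_max), 4)] += 1 / k
        hists.append(h)
    out = []
    for j in range(5):
        col = [h[j] for h in hists]
        out += [
            np.percentile(col, 25),
            np.mean(col),
            np.percentile(col, 50),
            np.percentile(col, 75),
        ]
    return np.array(out)


class TestNeighborDistances:
    def test_degenerate_inputs_zero_block(self):
        assert neighbor_distance_features([]).tolist() == [0.0] * 20
        assert neighbor_distance_features([TextRegion(0, 0, 5, 5)]).tolist() == [0.0] * 20
        same = [TextRegion(0, 0, 5, 5), TextRegion(2, 2, 4, 4)]  # overlapping: d_max 0
        assert neighbor_distance_features(same).tolist() == [0.0] * 20

    def test_collinear_regions_match_bruteforce(self):
        regions = [TextRegion(10 * i, 0, 10 * i + 4, 4) for i in range(4)]
        got = neighbor_distance_features(regions)
        assert got == pytest.approx(brute_force_distance_block(regions))
        assert len(got) == 20

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(2, 9))
    def test_random_regions_match_bruteforce(self, seed, n):
        rng = np.random.default_rng(seed)
        regions = []
        for _ in range(n):
            x0, y0 = rng.integers(0, 80, 2)
            regions.append(TextRegion(int(x0), int(y0), int(x0) + int(rng.integers(2, 9)), int(y0) + int(rng.integers(2, 9))))
        got = neighbor_distance_features(regions)
        assert got == pytest.approx(brute_force_distance_block(regions))


class TestExtractFeatures:
    def test_length_and_block_layout(self, table_figure):
        fv = extract_features(table_figure.image, table_figure.regions)
        assert len(fv) == FEATURE_DIM == 100
        sizes = {name: s.stop - s.start for name, s in BLOCK_SLICES.items()}
        assert sizes["entropy_h"] + sizes["entropy_v"] == 20
        assert sizes["freq_h"] + sizes["freq_v"] + sizes["structure_h"] + sizes["structure_v"] == 60
        assert sizes["distance"] == 20

    def test_blank_figure_degenerate_vector(self):
        img = np.full((64, 64), 255, np.uint8)
        fv = extract_features(img, [])
        assert fv.block("entropy_h").tolist() == [1] + [0] * 9
        assert fv.block("structure_v").tolist() == [1] + [0] * 9
        assert fv.block("freq_h").tolist() == [0.0] * 20
        assert fv.block("distance").tolist() == [0.0] * 20

    def test_deterministic_and_finite(self, table_figure):
        a = extract_features(table_figure.image, table_figure.regions)
        b = extract_features(table_figure.image, table_figure.regions)
        assert np.array_equal(a.values, b.values)
        assert np.all(np.isfinite(a.values)) and np.all(a.values >= 0)

    def test_histogram_blocks_sum_to_one(self, table_figure):
        fv = extract_features(table_figure.image, table_figure.regions)
        for name in ("entropy_h", "entropy_v", "structure_h", "structure_v"):
            assert fv.block(name).sum() == pytest.approx(1.0)

    def test_out_of_bounds_region_rejected(self):
        img = np.full((64, 64), 255, np.uint8)
        with pytest.raises(ValueError, match="bounds"):
            extract_features(img, [TextRegion(60, 60, 70, 70)])

    def test_translation_leaves_distance_block_unchanged(self):
        regions = [
            TextRegion(10, 10, 30, 16),
            TextRegion(50, 12, 70, 18),
            TextRegion(12, 40, 32, 46),
        ]
        shifted = [TextRegion(r.x0 + 15, r.y0 + 9, r.x1 + 15, r.y1 + 9) for r in regions]
        img = np.full((100, 120), 255, np.uint8)
        a = extract_features(img, regions)
        b = extract_features(img, shifted)
        assert a.block("distance") == pytest.approx(b.block("distance"))

    def test_wrong_length_vector_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(np.zeros(99))
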