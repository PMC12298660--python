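import numpy as np
import pytest

from marblesense.texture_lbp import (
    LBPConfig,
    _sample_offsets,
    lbp_code,
    lbp_histogram,
    to_grayscale,
    transition_count,
    uniform_bin_index,
)


def transition_count_oracle(code, P):
    """Brute-force circular scan of the bit string."""
    bits = [(code >> k) & 1 for k in range(P)]
    return sum(bits[k] != bits[(k + 1) % P] for k in range(P))


def histogram_oracle(gray, config):
    """Naive per-pixel double loop using the same sampling offsets."""
    gray = gray.astype(float)
    h, w = gray.shape
    R, P = config.R, config.P
    offsets = _sample_offsets(P, R)
    counts = np.zeros(config.n_bins)
    for i in range(R, h - R):
        for j in range(R, w - R):
            code = 0
            for k, (dx, dy) in enumerate(offsets):
                yy, xx = i + dy, j + dx
                y0, x0 = int(np.floor(yy)), int(np.floor(xx))
                fy, fx = yy - y0, xx - x0
                # full bilinear, skipping zero-weight corners so exact-integer
                # coordinates never index out of bounds
                val = 0.0
                for oy, wy in ((y0, 1 - fy), (y0 + 1, fy)):
                    for ox, wx in ((x0, 1 - fx), (x0 + 1, fx)):
                        if wy * wx:
                            val += wy * wx * gray[oy, ox]
                if val >= gray[i, j]:
                    code |= 1 << k
            counts[uniform_bin_index(code, P)] += 1
    return counts / counts.sum()


class TestGrayscale:
    @pytest.mark.parametrize("pixel,expected", [
        ((255, 255, 255), 255),
        ((0, 0, 0), 0),
        ((100, 150, 200), 141),  # round(29.9 + 88.05 + 22.8)
    ])
    def test_luma_formula(self, pixel, expected):
        block = np.array([[pixel]], dtype=np.uint8)
        assert to_grayscale(block)[0, 0] == expected


class TestLBPCode:
    def test_flat_patch_all_bits_set(self):
        assert lbp_code(100, [100] * 8) == 255

    def test_all_neighbors_below(self):
        assert lbp_code(200, [0] * 8) == 0

    def test_alternating_neighbors(self):
        # bit k set iff neighbor k >= 5: neighbors (9,1,9,1,...) -> bits 0,2,4,6
        assert lbp_code(5, [9, 1, 9, 1, 9, 1, 9, 1]) == 0b01010101

    def test_wrong_neighbor_count_rejected(self):
        with pytest.raises(ValueError):
            lbp_code(10, [1, 2, 3])


class TestTransitionsAndBins:
    @pytest.mark.parametrize("code,expected", [
        (0b00000000, 0), (0b11111111, 0), (0b00001111, 2), (0b01010101, 8),
    ])
    def test_transition_count_examples(self, code, expected):
        assert transition_count(code, 8) == expected

    def test_transition_count_matches_oracle_for_all_codes(self):
        for code in range(256):
            assert transition_count(code, 8) == transition_count_oracle(code, 8)

    def test_58_uniform_codes_for_p8(self):
        uniform = [c for c in range(256) if transition_count(c, 8) <= 2]
        assert len(uniform) == 58
        assert 58 == 8 * 7 + 2  # P(P-1) + 2

    def test_uniform_mapping_is_injective_and_ascending(self):
        uniform = [c for c in range(256) if transition_count(c, 8) <= 2]
        bins = [uniform_bin_index(c, 8) for c in uniform]
        assert bins == list(range(58))

    def test_non_uniform_codes_pool_into_bin_58(self):
        assert uniform_bin_index(0b01010101, 8) == 58
        for c in range(256):
            if transition_count(c, 8) > 2:
                assert uniform_bin_index(c, 8) == 58

    def test_out_of_range_code_rejected(self):
        with pytest.raises(ValueError):
            transition_count(256, 8)
        with pytest.raises(ValueError):
            uniform_bin_index(-1, 8)


class TestHistogram:
    def test_constant_block_masses_the_all_ones_bin(self):
        block = np.full((20, 20, 3), 90, dtype=np.uint8)
        hist = lbp_histogram(block, LBPConfig(8, 1))
        assert hist.bins[uniform_bin_index(255, 8)] == pytest.approx(1.0)

    @pytest.mark.parametrize("config", [LBPConfig(8, 1), LBPConfig(8, 2), LBPConfig(16, 2)])
    def test_bins_sum_to_one(self, random_block, config):
        hist = lbp_histogram(random_block, config)
        assert hist.bins.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("config", [LBPConfig(8, 1), LBPConfig(8, 2), LBPConfig(16, 2)])
    def test_interior_code_count(self, random_block, config):
        from marblesense.texture_lbp import lbp_code_image, to_grayscale

        codes = lbp_code_image(to_grayscale(random_block), config)
        s = random_block.shape[0]
        assert codes.size == (s - 2 * config.R) ** 2

    @pytest.mark.parametrize("config", [LBPConfig(8, 1), LBPConfig(8, 2), LBPConfig(16, 2)])
    def test_matches_double_loop_oracle(self, rng, config):
        block = rng.integers(0, 256, size=(24, 24, 3)).astype(np.uint8)
        hist = lbp_histogram(block, config)
        expected = histogram_oracle(to_grayscale(block).astype(float), config)
        assert hist.bins == pytest.approx(expected, abs=1e-12)

    def test_gray_shift_invariance(self, rng):
        gray_vals = rng.integers(50, 150, size=(30, 30), dtype=np.uint8)
        block = np.repeat(gray_vals[:, :, None], 3, axis=2)
        shifted = block + 40  # stays below 256
        h0 = lbp_histogram(block, LBPConfig(8, 1))
        h1 = lbp_histogram(shifted, LBPConfig(8, 1))
        assert h0.bins == pytest.approx(h1.bins)

    def test_p16_histogram_has_243_bins(self, random_block):
        hist = lbp_histogram(random_block, LBPConfig(16, 2))
        assert hist.bins.shape == (243,)

    def test_radius1_sampling_is_exact_on_integer_grid(self):
        # radius-1 offsets are the 3x3 integer neighbours, so bilinear
        # sampling there returns the neighbour values with no blending
        offsets = _sample_offsets(8, 1)
        assert all(dx == int(dx) and dy == int(dy) for dx, dy in offsets)
        assert sorted(offsets) == sorted(
            [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
        )

    def test_block_too_small_for_radius_rejected(self):
        with pytest.raises(ValueError):
            lbp_histogram(np.zeros((4, 4, 3), dtype=np.uint8), LBPConfig(16, 2))

    def test_unsupported_config_rejected(self):
        with pytest.raises(ValueError):
            LBPConfig(12, 3)

    def test_concatenated_image_level_export(self, rng):
        from marblesense.texture_lbp import concatenate_histograms

        hists = [
            lbp_histogram(rng.integers(0, 256, size=(16, 16, 3)).astype(np.uint8))
            for _ in range(55)
        ]
        joined = concatenate_histograms(hists)
        assert joined.shape == (55 * 59,)
        assert joined[:59] == pytest.approx(hists[0].bins)
        with pytest.raises(ValueError):
            concatenate_histograms([])
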