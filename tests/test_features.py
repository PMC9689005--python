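import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from entrostress.errors import ValidationError
from entrostress.features import (
    HSI_TRIM,
    TIR_TRIM,
    TrimSpec,
    compute_statistics,
    default_trims,
    extract_features,
    shannon_entropy,
    subsample_feature_dataset,
    trim_percentiles,
)
from entrostress.indices import IndexName, compute_all_indices, compute_index
from entrostress.masking import build_plant_mask


def brute_force_trim(values, lower, upper):
    """Independent oracle: keep values inside the percentile window."""
    lo = np.percentile(values, lower, method="linear")
    hi = np.percentile(values, 100 - upper, method="linear")
    return [v for v in values if lo <= v <= hi]


class TestTrimPercentiles:
    def test_1_to_100_with_defaults_matches_oracle(self):
        values = list(range(1, 101))
        kept = trim_percentiles(values, TrimSpec(1, 5))
        oracle = brute_force_trim(values, 1, 5)
        assert kept.tolist() == oracle
        assert kept.tolist() == list(range(2, 96))  # [P1, P95] = [1.99, 95.05]
        assert len(kept) == 94

    def test_zero_trim_is_identity(self):
        values = [3.0, 1.0, 2.0]
        assert trim_percentiles(values, TrimSpec(0, 0)).tolist() == values

    def test_constant_values_identity(self):
        assert trim_percentiles([5.0] * 10, TrimSpec(10, 10)).tolist() == [5.0] * 10

    def test_order_preserved(self):
        values = [50, 3, 97, 40, 60]
        kept = trim_percentiles(values, TrimSpec(10, 10))
        assert kept.tolist() == [v for v in values if v in set(brute_force_trim(values, 10, 10))]

    def test_never_empty_falls_back_to_median(self):
        # extreme trim on two very different values would keep nothing
        kept = trim_percentiles([0.0, 100.0], TrimSpec(49, 49))
        assert len(kept) >= 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            trim_percentiles([], TrimSpec(1, 1))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValidationError):
            TrimSpec(60, 40)
        with pytest.raises(ValidationError):
            TrimSpec(-1, 0)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(-1e6, 1e6, width=32), min_size=1, max_size=50),
        st.floats(0, 20),
        st.floats(0, 20),
    )
    def test_more_trimming_never_widens_range(self, values, lower, upper):
        mild = trim_percentiles(values, TrimSpec(lower / 2, upper / 2))
        harsh = trim_percentiles(values, TrimSpec(lower, upper))
        assert harsh.min() >= mild.min() - 1e-9
        assert harsh.max() <= mild.max() + 1e-9


class TestShannonEntropy:
    def test_uniform_eight_groups_three_bits(self):
        values = np.repeat(np.arange(8.0), 10) + 0.5
        assert shannon_entropy(values, n_bins=8) == pytest.approx(3.0)

    def test_constant_values_zero_entropy(self):
        assert shannon_entropy([2.5] * 7, n_bins=64) == 0.0

    def test_counts_1_1_2_is_one_point_five_bits(self):
        # bins hold counts (1, 1, 2): H = -0.25 log2 0.25 * 2 - 0.5 log2 0.5
        values = [0.1, 1.1, 2.1, 2.2]
        assert shannon_entropy(values, n_bins=3) == pytest.approx(1.5)

    def test_bounded_by_log2_nbins(self):
        rng = np.random.default_rng(3)
        for n_bins in (1, 4, 32):
            h = shannon_entropy(rng.random(500), n_bins=n_bins)
            assert 0.0 <= h <= math.log2(max(n_bins, 2)) + 1e-12 if n_bins > 1 else h == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(-100, 100, width=32), min_size=2, max_size=60),
        st.floats(0.01, 50),
        st.floats(-1e3, 1e3),
    )
    def test_invariant_under_increasing_affine_maps(self, values, scale, shift):
        arr = np.array(values, dtype=float)
        h0 = shannon_entropy(arr, 16)
        h1 = shannon_entropy(arr * scale + shift, 16)
        assert h0 == pytest.approx(h1, abs=1e-6)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            shannon_entropy([], 8)


class TestComputeStatistics:
    def test_hand_computed_values(self):
        s = compute_statistics([1.0, 2.0, 3.0])
        assert s.min == 1 and s.max == 3 and s.mean == 2
        assert s.std == pytest.approx(math.sqrt(2 / 3))  # population std
        assert s.max_min == 2

    def test_constant_input_degenerate(self):
        s = compute_statistics([4.2] * 9)
        assert s.std == 0 and s.max_min == 0 and s.entropy == 0

    def test_translation_shifts_location_only(self):
        rng = np.random.default_rng(5)
        values = rng.random(200)
        a, b = compute_statistics(values), compute_statistics(values + 7.5)
        assert b.mean == pytest.approx(a.mean + 7.5)
        assert b.min == pytest.approx(a.min + 7.5)
        assert b.max == pytest.approx(a.max + 7.5)
        assert b.std == pytest.approx(a.std)
        assert b.max_min == pytest.approx(a.max_min)
        assert b.entropy == pytest.approx(a.entropy, abs=1e-9)

    def test_max_min_identity(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            s = compute_statistics(rng.normal(size=50))
            assert s.max_min == s.max - s.min


class TestDefaults:
    def test_tir_trim_is_one_five(self):
        assert (TIR_TRIM.lower_pct, TIR_TRIM.upper_pct) == (1.0, 5.0)
        assert default_trims()["TIR"] == TIR_TRIM

    def test_hsi_trim_is_one_one(self):
        assert (HSI_TRIM.lower_pct, HSI_TRIM.upper_pct) == (1.0, 1.0)
        assert default_trims()["index"] == HSI_TRIM == default_trims()["channel"]


class TestExtractFeatures:
    def test_ten_indices_give_sixty_scalars(self, scenes_long):
        scene = scenes_long[0]
        images = compute_all_indices(scene.cube, tir=scene.tir)
        mask = build_plant_mask(images[IndexName.NDBLUE], 0.1)
        out = extract_features(images, mask)
        assert len(out) == 10
        assert sum(len(s.as_dict()) for s in out.values()) == 60

    def test_stat_invariants_on_real_output(self, scenes_long):
        scene = scenes_long[0]
        images = compute_all_indices(scene.cube, tir=scene.tir)
        mask = build_plant_mask(images[IndexName.NDBLUE], 0.1)
        for stats in extract_features(images, mask).values():
            assert stats.max >= stats.min
            assert stats.max_min == stats.max - stats.min
            assert stats.std >= 0
            assert 0 <= stats.entropy <= 6.0  # log2(64)


class TestSubsampleDataset:
    def test_row_count(self, table_long_small, scenes_long):
        # 7 days x 12 samples x 10 indices x 6 features
        assert len(table_long_small) == 7 * 12 * 10 * 6

    def test_deterministic_under_seed(self, scenes_long):
        t1 = subsample_feature_dataset(scenes_long, samples_per_day=3, seed=9)
        t2 = subsample_feature_dataset(scenes_long, samples_per_day=3, seed=9)
        assert t1.frame.equals(t2.frame)

    def test_fraction_one_single_sample_equals_extract_features(self, scenes_long):
        scene = scenes_long[0]
        table = subsample_feature_dataset([scene], fraction=1.0, samples_per_day=1, seed=0)
        images = compute_all_indices(scene.cube, tir=scene.tir)
        mask = build_plant_mask(images[IndexName.NDBLUE], 0.1)
        direct = extract_features(images, mask)
        frame = table.frame
        for name, stats in direct.items():
            for feat, value in stats.as_dict().items():
                sel = (frame["index_name"] == name.value) & (frame["feature_name"] == feat)
                assert frame.loc[sel, "value"].item() == pytest.approx(value, rel=1e-12)

    def test_max_min_identity_on_emitted_rows(self, table_long_small):
        wide = table_long_small.frame.pivot_table(
            index=["sample_id", "index_name"], columns="feature_name", values="value"
        )
        np.testing.assert_allclose(wide["max_min"], wide["max"] - wide["min"], rtol=1e-12)

    def test_invalid_fraction_rejected(self, scenes_long):
        with pytest.raises(ValidationError):
            subsample_feature_dataset(scenes_long, fraction=0.0)


def test_per_day_entropy_reproduces_state_trajectory(scenes_long):
    """Per-day G550 entropy follows the qualitative stress-state pattern."""
    H = {}
    for scene in scenes_long:
        g = compute_index(scene.cube, IndexName.GREEN)
        mask = build_plant_mask(compute_index(scene.cube, IndexName.NDBLUE), 0.1)
        from entrostress.masking import apply_mask

        H[scene.day] = shannon_entropy(trim_percentiles(apply_mask(g, mask), HSI_TRIM), 64)
    assert H[3] < H[1] < H[6]
    assert H[25] < H[19]
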