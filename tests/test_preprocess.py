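"""Background estimation, effective-point filtering, NFI normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lectinarray.panel import Lectin, LectinPanel
from lectinarray.preprocess import (
    BlockBackground,
    DegenerateBlockError,
    PreprocessError,
    aggregate_group,
    block_background,
    blocks_to_nfi,
    filter_effective,
    lectin_block_nfi,
)

from conftest import make_spots


class TestBlockBackground:
    def test_equal_backgrounds_give_zero_sd(self):
        spots = make_spots([500] * 3, backgrounds=[100, 100, 100])
        bg = block_background(spots)
        assert (bg.bg_mean, bg.bg_sd) == (100.0, 0.0)

    def test_hand_computed_mean_and_sample_sd(self, toy_block):
        bg = block_background(toy_block)
        assert bg.bg_mean == pytest.approx(100.0)
        assert bg.bg_sd == pytest.approx(10.0)  # sample SD of {90,100,110}

    def test_single_spot_block_is_an_error(self):
        with pytest.raises(PreprocessError, match=">= 2"):
            block_background(make_spots([500], backgrounds=[100]))

    def test_lectin_only_mode_excludes_controls(self):
        spots = make_spots([500, 500, 500, 500], backgrounds=[90, 110, 500, 500])
        spots.loc[2:, "Role"] = "marker"
        bg = block_background(spots, include_controls=False)
        assert bg.bg_mean == pytest.approx(100.0)


class TestFilterEffective:
    BG = BlockBackground(block=1, bg_mean=100.0, bg_sd=10.0)

    def test_worked_threshold_115(self):
        spots = make_spots([90, 114, 116, 200])
        surv = filter_effective(spots, self.BG, k=1.5)
        assert sorted(surv["F532 Median"]) == [116, 200]

    def test_threshold_is_inclusive(self):
        spots = make_spots([114.999, 115.0, 115.001])
        surv = filter_effective(spots, self.BG, k=1.5)
        assert sorted(surv["F532 Median"]) == [115.0, 115.001]

    def test_k_zero_keeps_everything_at_or_above_mean(self):
        spots = make_spots([99, 100, 101])
        surv = filter_effective(spots, self.BG, k=0.0)
        assert sorted(surv["F532 Median"]) == [100, 101]

    def test_all_flagged_spots_removed(self):
        spots = make_spots([200, 300, 400], flags=[-100, -100, -50])
        assert len(filter_effective(spots, self.BG, k=1.5)) == 0

    def test_alternative_below_reading(self):
        spots = make_spots([84, 86, 200])
        surv = filter_effective(spots, self.BG, k=1.5, direction="below")
        assert sorted(surv["F532 Median"]) == [86, 200]  # threshold 85

    @settings(max_examples=50, deadline=None)
    @given(
        fg=st.lists(st.floats(0, 1000, allow_nan=False), min_size=1, max_size=30),
        k1=st.floats(0, 5),
        k2=st.floats(0, 5),
    )
    def test_survivors_shrink_monotonically_in_k(self, fg, k1, k2):
        lo, hi = sorted([k1, k2])
        spots = make_spots(fg)
        s_lo = set(filter_effective(spots, self.BG, k=lo).index)
        s_hi = set(filter_effective(spots, self.BG, k=hi).index)
        assert s_hi <= s_lo


class TestLectinBlockNFI:
    panel3 = LectinPanel((Lectin("A"), Lectin("B"), Lectin("C")))

    def test_hand_computed_fractions(self):
        bg = BlockBackground(1, 0.0, 0.0)
        spots = make_spots([2, 3, 5], names=["A", "B", "C"])
        nfi, mask = lectin_block_nfi(spots, self.panel3, bg)
        assert np.allclose(nfi[["A", "B", "C"]], [0.2, 0.3, 0.5])
        assert mask.all()

    def test_equal_medians_give_uniform_nfi(self):
        bg = BlockBackground(1, 0.0, 0.0)
        spots = make_spots([4, 4, 4], names=["A", "B", "C"])
        nfi, _ = lectin_block_nfi(spots, self.panel3, bg)
        assert np.allclose(nfi, 1 / 3)

    def test_filtered_out_lectin_marked_non_effective_sum_still_one(self):
        bg = BlockBackground(1, 0.0, 0.0)
        spots = make_spots([2, 8], names=["A", "C"])  # B fully filtered
        nfi, mask = lectin_block_nfi(spots, self.panel3, bg)
        assert not mask["B"]
        assert np.isnan(nfi["B"])
        assert nfi[mask].sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_signal_filtered_is_degenerate(self):
        bg = BlockBackground(1, 100.0, 0.0)
        spots = make_spots([50, 60], names=["A", "B"])  # net floors to 0
        with pytest.raises(DegenerateBlockError):
            lectin_block_nfi(spots, self.panel3, bg)

    def test_even_survivor_count_uses_midpoint_median(self):
        bg = BlockBackground(1, 0.0, 0.0)
        spots = make_spots([10, 20, 30, 30], names=["A", "A", "B", "B"])
        nfi, _ = lectin_block_nfi(spots, self.panel3, bg)
        assert nfi["A"] == pytest.approx(15 / 45)


class TestScaleInvariance:
    @settings(max_examples=30, deadline=None)
    @given(
        scale=st.floats(0.01, 100),
        seed=st.integers(0, 2**16),
    )
    def test_nfi_invariant_to_global_intensity_scale(self, scale, seed, small_layout):
        rng = np.random.default_rng(seed)
        coords = sorted(small_layout.grid_map)
        base = pd.DataFrame(
            {
                "Slide": 1,
                "Block": [c[0] for c in coords],
                "Row": [c[1] for c in coords],
                "Column": [c[2] for c in coords],
                "Role": [small_layout.grid_map[c][0] for c in coords],
                "Name": [small_layout.grid_map[c][1] for c in coords],
                "F532 Median": rng.uniform(200, 5000, len(coords)),
                "B532 Median": rng.uniform(50, 150, len(coords)),
                "Flags": 0,
            }
        )
        scaled = base.assign(**{
            "F532 Median": base["F532 Median"] * scale,
            "B532 Median": base["B532 Median"] * scale,
        })
        a = blocks_to_nfi([base], small_layout).values
        b = blocks_to_nfi([scaled], small_layout).values
        pd.testing.assert_frame_equal(a, b, atol=1e-9, rtol=1e-7)


class TestAggregateGroup:
    def _nfi_matrix(self, columns):
        values = pd.DataFrame(columns)
        mask = values.notna()
        from lectinarray.preprocess import NFIMatrix

        return NFIMatrix(values=values, mask=mask)

    def test_identical_columns_have_zero_sd(self):
        col = pd.Series({"A": 0.25, "B": 0.75})
        nfi = self._nfi_matrix({f"b{i}": col for i in range(9)})
        g = aggregate_group("HV", nfi)
        assert np.allclose(g.summary["sd"], 0.0)
        assert np.allclose(g.summary["mean_nfi"], col)
        assert (g.summary["n_blocks"] == 9).all()

    def test_hand_computed_mean_and_sd(self):
        vals = [0.10, 0.12, 0.14]
        nfi = self._nfi_matrix({f"b{i}": pd.Series({"A": v}) for i, v in enumerate(vals)})
        g = aggregate_group("HV", nfi)
        assert g.summary.loc["A", "mean_nfi"] == pytest.approx(0.12)
        assert g.summary.loc["A", "sd"] == pytest.approx(0.02)

    def test_lectin_effective_in_one_block_flagged_unusable(self):
        cols = {
            "b0": pd.Series({"A": 0.5, "B": 0.5}),
            "b1": pd.Series({"A": 1.0, "B": np.nan}),
            "b2": pd.Series({"A": 1.0, "B": np.nan}),
        }
        g = aggregate_group("HV", self._nfi_matrix(cols))
        assert not g.summary.loc["B", "usable"]
        assert g.summary.loc["A", "usable"]
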