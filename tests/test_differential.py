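"""Fold-change categorization, t/ANOVA behavior, cross-type patterns."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lectinarray.differential import (
    DOWN,
    EVEN,
    UP,
    DifferentialError,
    FoldUndefinedError,
    Thresholds,
    call_set,
    calls_from_summary,
    categorize,
    cross_type,
    fold_change,
    multigroup_anova,
    pairwise_t,
    t_from_summary,
    table2_style,
)
from lectinarray.preprocess import GroupNFI


def permutation_p(x: np.ndarray, y: np.ndarray, n_perm: int, rng) -> float:
    """Independent oracle: permutation distribution of the mean difference."""
    pooled = np.concatenate([x, y])
    obs = abs(x.mean() - y.mean())
    idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    perm = pooled[idx]
    diffs = np.abs(perm[:, : len(x)].mean(axis=1) - perm[:, len(x):].mean(axis=1))
    return (1 + np.sum(diffs >= obs - 1e-12)) / (n_perm + 1)


def make_group(label, columns):
    values = pd.DataFrame(columns)
    n = values.notna().sum(axis=1).astype(int)
    summary = pd.DataFrame(
        {
            "mean_nfi": values.mean(axis=1),
            "sd": values.std(axis=1, ddof=1),
            "n_blocks": n,
            "usable": n >= 2,
        }
    )
    return GroupNFI(group=label, blocks=values, summary=summary)


class TestFoldChange:
    def test_identity(self):
        assert fold_change(0.2, 0.2) == pytest.approx(1.0)

    def test_simple_ratio(self):
        assert fold_change(0.3, 0.2) == pytest.approx(1.5)

    def test_zero_denominator_not_comparable(self):
        with pytest.raises(FoldUndefinedError):
            fold_change(0.3, 0.0)

    @given(a=st.floats(1e-6, 1.0), b=st.floats(1e-6, 1.0))
    def test_antisymmetry(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)


class TestPairwiseT:
    def test_identical_samples_give_p_one(self):
        x = np.array([0.1, 0.2, 0.3])
        assert pairwise_t(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_textbook_pooled_t(self):
        # pooled t for {0.10,0.11,0.12} vs {0.20,0.21,0.22}:
        # means differ by 0.1, pooled SD 0.01, t = 0.1/(0.01*sqrt(2/3)),
        # df = 4 -> p computed from the t CDF independently
        from scipy import stats as ss

        x = np.array([0.10, 0.11, 0.12])
        y = np.array([0.20, 0.21, 0.22])
        t_stat = (x.mean() - y.mean()) / (0.01 * np.sqrt(2 / 3))
        expected = 2 * ss.t.sf(abs(t_stat), df=4)
        assert pairwise_t(x, y) == pytest.approx(expected, abs=1e-6)

    def test_agrees_with_permutation_oracle_on_small_samples(self):
        rng = np.random.default_rng(1234)
        diffs = []
        for _ in range(10):
            x = rng.normal(0, 1, 12)
            y = rng.normal(0.4, 1, 12)
            p_t = pairwise_t(x, y)
            p_perm = permutation_p(x, y, 20000, rng)
            diffs.append(abs(p_t - p_perm))
        assert max(diffs) < 0.03

    def test_fewer_than_two_replicates_unusable(self):
        assert np.isnan(pairwise_t(np.array([1.0]), np.array([1.0, 2.0])))

    def test_welch_option_differs_under_unequal_variance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.1, 5)
        y = rng.normal(0.5, 3.0, 15)
        assert pairwise_t(x, y, equal_var=True) != pairwise_t(x, y, equal_var=False)

    def test_summary_stat_t_matches_raw_t(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 1, 9), rng.normal(0.5, 1.2, 9)
        p_raw = pairwise_t(x, y)
        p_sum = t_from_summary(
            x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y)
        )
        assert p_sum == pytest.approx(p_raw, abs=1e-12)


class TestAnova:
    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 9), rng.normal(0.3, 1, 9)
        assert multigroup_anova([x, y]) == pytest.approx(pairwise_t(x, y), abs=1e-9)

    def test_degenerate_identical_values_p_one(self):
        assert multigroup_anova([np.ones(3), np.ones(4)]) == 1.0

    def test_p_decreases_with_planted_shift(self):
        rng = np.random.default_rng(3)
        base = [rng.normal(0, 1, 9) for _ in range(2)]
        ps = []
        for shift in [0.0, 0.5, 1.0, 2.0, 4.0]:
            groups = [base[0], base[1] + shift]
            ps.append(multigroup_anova(groups))
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_requires_two_replicates_per_group(self):
        with pytest.raises(DifferentialError):
            multigroup_anova([np.array([1.0]), np.array([1.0, 2.0])])


class TestCategorize:
    @pytest.mark.parametrize(
        "fold,p,expected",
        [
            (6.707, 0.001, UP),       # strong published-style up-regulation
            (1.5, 0.01, UP),          # boundary inclusive
            (0.67, 0.01, DOWN),       # boundary inclusive
            (1.0, 0.001, EVEN),
            (0.5, 0.2, EVEN),         # large fold but not significant
            (2.0, 0.05, EVEN),        # alpha strict
            (1.499999, 0.001, EVEN),
        ],
    )
    def test_criteria(self, fold, p, expected):
        assert categorize(fold, p) == expected

    @given(
        f1=st.floats(0.01, 100),
        f2=st.floats(0.01, 100),
        p=st.floats(0, 0.049),
    )
    def test_monotone_in_fold_at_fixed_significant_p(self, f1, f2, p):
        lo, hi = sorted([f1, f2])
        order = {DOWN: 0, EVEN: 1, UP: 2}
        assert order[categorize(lo, p)] <= order[categorize(hi, p)]

    @given(f=st.floats(0.01, 100), p=st.floats(0.05, 1))
    def test_never_differential_when_not_significant(self, f, p):
        assert categorize(f, p) == EVEN

    def test_reciprocal_thresholds_make_up_down_symmetric(self):
        thr = Thresholds(up=1.5, down=1 / 1.5)
        rng = np.random.default_rng(0)
        for _ in range(200):
            fold = float(rng.uniform(0.2, 5))
            p = float(rng.uniform(0, 0.1))
            a = categorize(fold, p, thr)
            b = categorize(1 / fold, p, thr)
            assert {a, b} in ({UP, DOWN}, {EVEN})


class TestCallSet:
    def test_no_effects_no_differential_lectins(self):
        cols = {f"b{i}": pd.Series({"A": 0.5, "B": 0.5}) for i in range(9)}
        nfis = {g: make_group(g, cols) for g in ["HV", "LC"]}
        cs = call_set(nfis, ["HV", "LC"])
        assert cs.differential_lectins == set()

    def test_pair_orientation_and_table_format(self):
        hv = {f"b{i}": pd.Series({"A": 0.2 + 0.001 * i, "B": 0.8 - 0.001 * i}) for i in range(9)}
        lc = {f"b{i}": pd.Series({"A": 0.4 + 0.001 * i, "B": 0.45 - 0.001 * i}) for i in range(9)}
        nfis = {"HV": make_group("HV", hv), "LC": make_group("LC", lc)}
        cs = call_set(nfis, ["HV", "LC"])
        row = cs.calls[(cs.calls.lectin == "A") & (cs.calls.pair == "LC/HV")].iloc[0]
        assert row["fold_change"] == pytest.approx(0.404 / 0.204, rel=1e-3)
        assert row["category"] == UP
        table = table2_style(cs)
        assert table.loc["A", "LC/HV"].endswith("↑")
        assert table.loc["B", "LC/HV"].endswith("↓")

    def test_unusable_lectin_reported_not_comparable(self):
        hv = {
            "b0": pd.Series({"A": 0.5, "B": 0.5}),
            "b1": pd.Series({"A": 1.0, "B": np.nan}),
            "b2": pd.Series({"A": 1.0, "B": np.nan}),
        }
        lc = {f"b{i}": pd.Series({"A": 0.5, "B": 0.5}) for i in range(3)}
        nfis = {"HV": make_group("HV", hv), "LC": make_group("LC", lc)}
        cs = call_set(nfis, ["HV", "LC"])
        assert (
            cs.calls[cs.calls.lectin == "B"]["category"].iloc[0] == "not_comparable"
        )

    def test_anova_attached_for_three_groups(self):
        rng = np.random.default_rng(0)
        nfis = {
            g: make_group(
                g, {f"b{i}": pd.Series({"A": rng.uniform(0.4, 0.6)}) for i in range(9)}
            )
            for g in ["HV", "BPD", "LC"]
        }
        cs = call_set(nfis, ["HV", "BPD", "LC"])
        assert cs.anova_p is not None and 0 <= cs.anova_p["A"] <= 1

    def test_bh_correction_recorded_and_less_liberal(self):
        rng = np.random.default_rng(4)
        hv = {f"b{i}": pd.Series({f"L{j}": rng.uniform(0.05, 0.15) for j in range(8)}) for i in range(9)}
        lc = {f"b{i}": pd.Series({f"L{j}": rng.uniform(0.05, 0.15) for j in range(8)}) for i in range(9)}
        nfis = {"HV": make_group("HV", hv), "LC": make_group("LC", lc)}
        plain = call_set(nfis, ["HV", "LC"])
        bh = call_set(nfis, ["HV", "LC"], correction="bh")
        assert bh.metadata["correction"] == "bh"
        assert (bh.calls["p_adjusted"] >= plain.calls["p_value"] - 1e-12).all()


class TestCallsFromSummary:
    def test_summary_table_reproduces_raw_calls(self):
        rng = np.random.default_rng(11)
        hv = {f"b{i}": pd.Series(rng.uniform(0.1, 0.3, 4), index=list("ABCD")) for i in range(9)}
        lc = {f"b{i}": pd.Series(rng.uniform(0.1, 0.3, 4), index=list("ABCD")) for i in range(9)}
        nfis = {"HV": make_group("HV", hv), "LC": make_group("LC", lc)}
        raw = call_set(nfis, ["HV", "LC"])
        summary = pd.concat(
            [
                nfis[g].summary.assign(group=g).rename_axis("lectin").reset_index()
                for g in nfis
            ]
        )[["group", "lectin", "mean_nfi", "sd", "n_blocks"]]
        from_sum = calls_from_summary(summary, ["HV", "LC"])
        merged = raw.calls.merge(from_sum.calls, on=["lectin", "pair"], suffixes=("_raw", "_sum"))
        assert np.allclose(merged["p_value_raw"], merged["p_value_sum"], atol=1e-9)
        assert (merged["category_raw"] == merged["category_sum"]).all()

    def test_missing_column_raises(self):
        bad = pd.DataFrame({"group": ["HV"], "lectin": ["A"], "mean_nfi": [0.5]})
        with pytest.raises(DifferentialError, match="sd"):
            calls_from_summary(bad, ["HV", "LC"])


class TestCrossType:
    def _type(self, label, levels, n=9, jitter=0.002, seed=0):
        rng = np.random.default_rng(seed)
        cols = {}
        for i in range(n):
            noisy = {k: v * (1 + jitter * rng.standard_normal()) for k, v in levels.items()}
            total = sum(noisy.values())
            cols[f"b{i}"] = pd.Series({k: v / total for k, v in noisy.items()})
        return make_group(label, cols)

    def test_identical_profiles_give_no_patterns(self):
        levels = {"X": 1.0, "Y": 2.0, "Z": 3.0}
        types = {t: self._type(t, levels, seed=i) for i, t in enumerate(["SCLC", "ADC", "SqCC"])}
        report = cross_type(types)
        assert (report["pattern"] == EVEN).all()

    def test_up_in_two_types_vs_third(self):
        base = {"X": 1.0, "Y": 2.0, "Z": 3.0}
        up = {"X": 2.0, "Y": 2.0, "Z": 3.0}
        types = {
            "SCLC": self._type("SCLC", base, seed=1),
            "ADC": self._type("ADC", up, seed=2),
            "SqCC": self._type("SqCC", up, seed=3),
        }
        report = cross_type(types)
        assert report.loc["X", "pattern"] == "decreased_in_SCLC_vs_rest"
        assert report.loc["X", "dual"] == "increased_in_ADC+SqCC_vs_SCLC"

    def test_down_in_one_type_vs_rest(self):
        base = {"X": 1.0, "Y": 2.0, "Z": 3.0}
        down = {"X": 1.0, "Y": 0.9, "Z": 3.0}
        types = {
            "SCLC": self._type("SCLC", base, seed=1),
            "ADC": self._type("ADC", down, seed=2),
            "SqCC": self._type("SqCC", base, seed=3),
        }
        report = cross_type(types)
        assert report.loc["Y", "pattern"] == "decreased_in_ADC_vs_rest"
        assert report.loc["Y", "dual"] == "increased_in_SCLC+SqCC_vs_ADC"

    def test_mismatched_panels_rejected(self):
        a = self._type("SCLC", {"X": 1.0, "Y": 2.0})
        b = self._type("ADC", {"X": 1.0, "Q": 2.0})
        with pytest.raises(DifferentialError, match="panel"):
            cross_type({"SCLC": a, "ADC": b})
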