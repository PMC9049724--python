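"""Fold-change / significance calling of differential glycopatterns.

A lectin's signal is called **up** between two groups when the ratio of
mean NFIs is >= 1.5 and the two-sided Student's t test over replicate
blocks gives p < 0.05; **down** when the ratio is <= 0.67 with p < 0.05;
otherwise **even**.  Both thresholds are inclusive and configurable.
Note the published down threshold 0.67 is not exactly 1/1.5, so the
up/down categories are not perfectly reciprocal under the defaults.

No multiple-testing correction is applied by default (matching the
original analysis across the 37-lectin panel); an optional
Benjamini-Hochberg flag is provided and recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Thresholds",
    "PairwiseCall",
    "CallSet",
    "DifferentialError",
    "FoldUndefinedError",
    "fold_change",
    "pairwise_t",
    "t_from_summary",
    "multigroup_anova",
    "categorize",
    "call_set",
    "calls_from_summary",
    "cross_type",
    "table2_style",
    "UP",
    "DOWN",
    "EVEN",
]

UP, DOWN, EVEN = "up", "down", "even"


class DifferentialError(ValueError):
    pass


class FoldUndefinedError(DifferentialError):
    """Denominator mean NFI is zero: fold change not comparable."""


@dataclass(frozen=True)
class Thresholds:
    """Fold and significance cut-offs for categorization."""

    up: float = 1.5
    down: float = 0.67
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.down < 1 < self.up:
            raise DifferentialError(f"need down < 1 < up, got down={self.down}, up={self.up}")
        if not 0 < self.alpha < 1:
            raise DifferentialError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class PairwiseCall:
    lectin: str
    group_a: str
    group_b: str
    fold_change: float
    p_value: float
    category: str


@dataclass
class CallSet:
    """All pairwise calls for one comparison design."""

    design: list[str]
    calls: pd.DataFrame  # lectin, pair, group_a, group_b, fold, p, category
    anova_p: pd.Series | None
    thresholds: Thresholds
    metadata: dict = field(default_factory=dict)

    @property
    def differential_lectins(self) -> set[str]:
        sel = self.calls["category"].isin([UP, DOWN])
        return set(self.calls.loc[sel, "lectin"])


def fold_change(mean_a: float, mean_b: float) -> float:
    """Ratio of mean NFIs, group a relative to group b."""
    if mean_b == 0:
        raise FoldUndefinedError("denominator mean NFI is zero")
    return mean_a / mean_b


def pairwise_t(
    blocks_a: np.ndarray,
    blocks_b: np.ndarray,
    equal_var: bool = True,
) -> float:
    """Two-sided Student's t p-value over replicate NFIs.

    Pooled-variance by default; ``equal_var=False`` selects Welch.
    Returns NaN when either side has fewer than two replicates.  The
    zero-variance degenerate cases resolve by limit: equal means -> 1,
    different means -> 0.
    """
    a = np.asarray(blocks_a, dtype=float)
    b = np.asarray(blocks_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def t_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int,
    equal_var: bool = True,
) -> float:
    """Two-sided t p-value from summary statistics (mean, SD, n).

    Used to re-apply the calling criteria to published mean +/- SD NFI
    tables where raw replicates are unavailable.
    """
    if n_a < 2 or n_b < 2:
        return float("nan")
    if sd_a == 0 and sd_b == 0:
        return 1.0 if mean_a == mean_b else 0.0
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=equal_var)
    return float(res.pvalue)


def multigroup_anova(groups: list[np.ndarray]) -> float:
    """One-way fixed-effects ANOVA p-value across >= 2 groups.

    With exactly two groups this is the pooled t test (F = t^2).  If all
    values are identical the p-value is 1 by convention.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise DifferentialError("ANOVA needs >= 2 groups with >= 2 replicates each")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 1.0
    if all(np.var(a) == 0 for a in arrays):
        return 0.0
    return float(stats.f_oneway(*arrays).pvalue)


def categorize(fold: float, p_value: float, thresholds: Thresholds = Thresholds()) -> str:
    """Apply the fold + significance criteria; boundaries inclusive."""
    if not np.isfinite(fold):
        raise DifferentialError(f"fold change must be finite, got {fold}")
    if np.isnan(p_value):
        return EVEN
    if fold >= thresholds.up and p_value < thresholds.alpha:
        return UP
    if fold <= thresholds.down and p_value < thresholds.alpha:
        return DOWN
    return EVEN


def _design_pairs(design: list[str]) -> list[tuple[str, str]]:
    # (numerator, denominator): later group in design order over earlier,
    # so design [HV, BPD] yields the pair "BPD/HV"
    return [(later, earlier) for earlier, later in combinations(design, 2)]


def _apply_correction(calls: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    ok = calls["p_value"].notna()
    adj = calls["p_value"].copy()
    adj[ok] = stats.false_discovery_control(calls.loc[ok, "p_value"], method="bh")
    calls = calls.assign(p_adjusted=adj)
    calls["category"] = [
        categorize(f, p, thresholds) if np.isfinite(f) else "not_comparable"
        for f, p in zip(calls["fold_change"], calls["p_adjusted"])
    ]
    return calls


def call_set(
    group_nfis: dict,
    design: list[str],
    thresholds: Thresholds = Thresholds(),
    equal_var: bool = True,
    correction: str | None = None,
) -> CallSet:
    """Compare every ordered pair of groups in the design.

    *group_nfis* maps group label to a
    :class:`~lectinarray.preprocess.GroupNFI`.  For each pair the later
    design group is the numerator (e.g. design ``[HV, BPD]`` yields the
    pair ``BPD/HV``).  Lectins unusable in either group are reported as
    ``not_comparable``.  With > 2 groups a one-way ANOVA p per lectin is
    attached (it does not gate the pairwise categories).
    """
    if len(design) < 2:
        raise DifferentialError("need >= 2 groups to compare")
    missing = [g for g in design if g not in group_nfis]
    if missing:
        raise DifferentialError(f"design group(s) without NFI data: {missing}")
    if correction not in (None, "bh"):
        raise DifferentialError(f"unknown correction {correction!r}")

    lectins = list(group_nfis[design[0]].blocks.index)
    rows = []
    for a, b in _design_pairs(design):
        ga, gb = group_nfis[a], group_nfis[b]
        for lectin in lectins:
            usable = bool(ga.summary.loc[lectin, "usable"] and gb.summary.loc[lectin, "usable"])
            mean_a = ga.summary.loc[lectin, "mean_nfi"]
            mean_b = gb.summary.loc[lectin, "mean_nfi"]
            if not usable or pd.isna(mean_a) or pd.isna(mean_b) or mean_b == 0:
                rows.append((lectin, f"{a}/{b}", a, b, np.nan, np.nan, "not_comparable"))
                continue
            fold = fold_change(mean_a, mean_b)
            p = pairwise_t(ga.replicates(lectin), gb.replicates(lectin), equal_var=equal_var)
            rows.append((lectin, f"{a}/{b}", a, b, fold, p, categorize(fold, p, thresholds)))
    calls = pd.DataFrame(
        rows, columns=["lectin", "pair", "group_a", "group_b", "fold_change", "p_value", "category"]
    )
    if correction == "bh":
        calls = _apply_correction(calls, thresholds)

    anova_p = None
    if len(design) > 2:
        vals = {}
        for lectin in lectins:
            reps = [group_nfis[g].replicates(lectin) for g in design]
            if all(len(r) >= 2 for r in reps):
                vals[lectin] = multigroup_anova(reps)
            else:
                vals[lectin] = np.nan
        anova_p = pd.Series(vals, name="anova_p")

    return CallSet(
        design=list(design),
        calls=calls,
        anova_p=anova_p,
        thresholds=thresholds,
        metadata={
            "test": "pooled-t" if equal_var else "welch-t",
            "correction": correction or "none",
            "up_threshold": thresholds.up,
            "down_threshold": thresholds.down,
            "alpha": thresholds.alpha,
        },
    )


def calls_from_summary(
    summary: pd.DataFrame,
    design: list[str],
    thresholds: Thresholds = Thresholds(),
    equal_var: bool = True,
) -> CallSet:
    """Re-apply the calling criteria to a mean +/- SD summary table.

    *summary* needs columns ``group, lectin, mean_nfi, sd, n_blocks`` —
    the structure of published per-group NFI summary tables.  The t test
    runs from summary statistics, so calls are exactly those the raw
    replicates would have produced under the pooled-t model.
    """
    required = {"group", "lectin", "mean_nfi", "sd", "n_blocks"}
    missing = required - set(summary.columns)
    if missing:
        raise DifferentialError(f"summary table missing column(s): {sorted(missing)}")
    stats_by_group = {
        g: sub.set_index("lectin") for g, sub in summary.groupby("group")
    }
    bad = [g for g in design if g not in stats_by_group]
    if bad:
        raise DifferentialError(f"design group(s) absent from summary: {bad}")
    lectins = list(stats_by_group[design[0]].index)
    rows = []
    for a, b in _design_pairs(design):
        sa, sb = stats_by_group[a], stats_by_group[b]
        for lectin in lectins:
            ma, mb = sa.loc[lectin, "mean_nfi"], sb.loc[lectin, "mean_nfi"]
            if mb == 0:
                rows.append((lectin, f"{a}/{b}", a, b, np.nan, np.nan, "not_comparable"))
                continue
            fold = fold_change(ma, mb)
            p = t_from_summary(
                ma, sa.loc[lectin, "sd"], int(sa.loc[lectin, "n_blocks"]),
                mb, sb.loc[lectin, "sd"], int(sb.loc[lectin, "n_blocks"]),
                equal_var=equal_var,
            )
            rows.append((lectin, f"{a}/{b}", a, b, fold, p, categorize(fold, p, thresholds)))
    calls = pd.DataFrame(
        rows, columns=["lectin", "pair", "group_a", "group_b", "fold_change", "p_value", "category"]
    )
    return CallSet(
        design=list(design),
        calls=calls,
        anova_p=None,
        thresholds=thresholds,
        metadata={"test": "pooled-t(summary)" if equal_var else "welch-t(summary)",
                  "correction": "none"},
    )


def table2_style(call_set_: CallSet, float_fmt: str = "{:.3f}") -> pd.DataFrame:
    """Fold + arrow matrix (lectin rows, pair columns); em dash for even."""
    arrows = {UP: "↑", DOWN: "↓"}
    def cell(row):
        if row["category"] in arrows:
            return float_fmt.format(row["fold_change"]) + arrows[row["category"]]
        return "—"
    data = call_set_.calls.assign(cell=call_set_.calls.apply(cell, axis=1))
    table = data.pivot(index="lectin", columns="pair", values="cell")
    ordered_pairs = [f"{a}/{b}" for a, b in _design_pairs(call_set_.design)]
    return table.reindex(columns=ordered_pairs)


def cross_type(
    type_nfis: dict,
    thresholds: Thresholds = Thresholds(),
    equal_var: bool = True,
) -> pd.DataFrame:
    """Classify each lectin's behavior across cancer types.

    *type_nfis* maps type label (e.g. SCLC, ADC, SqCC) to a type-level
    :class:`~lectinarray.preprocess.GroupNFI`.  Using the same fold +
    significance machinery between type means, each lectin is placed in
    one of:

    - ``increased_in_{A}_vs_rest`` / ``decreased_in_{A}_vs_rest`` — type
      A differs in that direction from every other type, while the other
      types are mutually even;
    - ``even`` — every pairwise comparison even;
    - ``mixed`` — any other combination.

    Because "decreased in C vs A and B" and "increased in A and B vs C"
    describe the same data, the report also carries the ``dual`` column
    with the majority-perspective phrasing of each minority pattern
    (e.g. ``increased_in_ADC+SqCC_vs_SCLC``).
    """
    types = list(type_nfis)
    if len(types) < 2:
        raise DifferentialError("need >= 2 types")
    panels = [tuple(nfi.blocks.index) for nfi in type_nfis.values()]
    if len(set(panels)) != 1:
        raise DifferentialError("type NFI tables use mismatched lectin panels")
    cs = call_set(type_nfis, types, thresholds=thresholds, equal_var=equal_var)

    def classify(lectin: str) -> tuple[str, str]:
        cats = {}
        for _, row in cs.calls[cs.calls["lectin"] == lectin].iterrows():
            flipped = {UP: DOWN, DOWN: UP}.get(row["category"], row["category"])
            cats[(row["group_a"], row["group_b"])] = row["category"]
            cats[(row["group_b"], row["group_a"])] = flipped
        if all(c == EVEN for c in cats.values()):
            return EVEN, EVEN
        if any(c == "not_comparable" for c in cats.values()):
            return "mixed", "mixed"
        for t in types:
            others = [o for o in types if o != t]
            vs = [cats[(t, o)] for o in others]
            among_even = all(cats[(a, b)] == EVEN for a, b in combinations(others, 2))
            if among_even and all(c == vs[0] for c in vs) and vs[0] in (UP, DOWN):
                word = "increased" if vs[0] == UP else "decreased"
                dual_word = "decreased" if vs[0] == UP else "increased"
                return (
                    f"{word}_in_{t}_vs_rest",
                    f"{dual_word}_in_{'+'.join(others)}_vs_{t}",
                )
        return "mixed", "mixed"

    lectins = list(type_nfis[types[0]].blocks.index)
    patterns, duals = zip(*(classify(l) for l in lectins))
    out = pd.DataFrame({"lectin": lectins, "pattern": patterns, "dual": duals})
    for _, row in cs.calls.iterrows():
        out.loc[out["lectin"] == row["lectin"], f"fold {row['pair']}"] = row["fold_change"]
        out.loc[out["lectin"] == row["lectin"], f"p {row['pair']}"] = row["p_value"]
    return out.set_index("lectin")
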