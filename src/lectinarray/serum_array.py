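"""Reverse-phase serum microarray: the individual-sample validation arm.

Here the format is inverted relative to the lectin array: individual
serum samples are spotted (triplicate per block, two blocks per slide,
so six replicate spots per sample) and the whole slide is probed with a
single Cy3-labeled lectin.  Analysis per sample: remove spots below the
block background mean + 2 SD (the stricter k = 2 filter), take the
median of the surviving background-subtracted foregrounds, then compare
the per-sample medians across subject groups with t tests / ANOVA.

Filtering is the identical contract as the lectin-array stage — the
same implementation is reused with k = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import BlockBackground, PreprocessError, block_background, filter_effective
from .differential import multigroup_anova, pairwise_t
from .simulate import DROPOUT_FLAG, SimulationError, _background, _lognormal_factor, _sub_seed

__all__ = [
    "SerumSimConfig",
    "filter_effective_serum",
    "sample_median",
    "summarize_samples",
    "group_compare",
    "simulate_serum_array",
    "concordance",
    "SERUM_COLUMNS",
]

SERUM_COLUMNS = [
    "Sample",
    "Group",
    "Slide",
    "Block",
    "Replicate",
    "F532 Median",
    "B532 Median",
    "Flags",
]


@dataclass(frozen=True)
class SerumSimConfig:
    """Synthetic reverse-phase array emulating the validation design.

    Defaults: 30 individual samples per group, lognormal
    inter-individual variation with CV 0.3 around the group mean,
    triplicate spots in each of two blocks per sample, 10% spot CV.
    """

    group_means: dict[str, float]
    n_samples: int = 30
    inter_cv: float = 0.3
    spot_cv: float = 0.10
    background_mean: float = 300.0
    background_sd: float = 30.0
    dropout_rate: float = 0.0
    blocks_per_sample: int = 2
    spots_per_block: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.group_means.values()):
            raise SimulationError("group means must be > 0")
        if self.inter_cv < 0 or self.spot_cv < 0 or self.background_sd < 0:
            raise SimulationError("CVs and background_sd must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise SimulationError("dropout_rate must be in [0, 1)")
        if self.n_samples < 1:
            raise SimulationError("n_samples must be >= 1")


def simulate_serum_array(config: SerumSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the spotted-serum slide set.

    Per sample: true level = group mean x LN(1, inter_cv); each of its
    replicate spots adds multiplicative spot noise and additive
    background.  Returns (spot table, ground-truth per-sample levels).
    Deterministic for a fixed seed; each group draws its own sub-stream.
    """
    spot_rows = []
    truth_rows = []
    spots_per_sample = config.blocks_per_sample * config.spots_per_block
    for group, mean in config.group_means.items():
        rng = _sub_seed(config.seed, group, 0)
        levels = mean * _lognormal_factor(rng, config.inter_cv, config.n_samples)
        for i, level in enumerate(levels, start=1):
            sample = f"{group}-{i:03d}"
            truth_rows.append({"sample": sample, "group": group, "true_level": level})
            noise = _lognormal_factor(rng, config.spot_cv, spots_per_sample)
            fg_bg = _background(rng, config.background_mean, config.background_sd, spots_per_sample)
            bgs = _background(rng, config.background_mean, config.background_sd, spots_per_sample)
            flags = np.zeros(spots_per_sample, dtype=int)
            if config.dropout_rate > 0:
                flags[rng.random(spots_per_sample) < config.dropout_rate] = DROPOUT_FLAG
            j = 0
            for block in range(1, config.blocks_per_sample + 1):
                for rep in range(1, config.spots_per_block + 1):
                    spot_rows.append(
                        {
                            "Sample": sample,
                            "Group": group,
                            "Slide": 1,
                            "Block": block,
                            "Replicate": rep,
                            "F532 Median": level * noise[j] + fg_bg[j],
                            "B532 Median": bgs[j],
                            "Flags": flags[j],
                        }
                    )
                    j += 1
    spots = pd.DataFrame(spot_rows, columns=SERUM_COLUMNS)
    truth = pd.DataFrame(truth_rows)
    return spots, truth


def filter_effective_serum(
    spots: pd.DataFrame,
    bg: BlockBackground,
    k: float = 2.0,
) -> pd.DataFrame:
    """Effective serum spots: the shared filter contract at k = 2."""
    return filter_effective(spots, bg, k=k, direction="above")


def sample_median(survivors: pd.DataFrame, bg_mean: float) -> float:
    """Median of background-subtracted foregrounds for one sample.

    Raises :class:`PreprocessError` when no spot survived (the sample is
    flagged no-signal upstream and excluded from group statistics).
    """
    if len(survivors) == 0:
        raise PreprocessError("no effective data points for sample")
    net = (survivors["F532 Median"] - bg_mean).clip(lower=0)
    return float(net.median())


def summarize_samples(spots: pd.DataFrame, k: float = 2.0) -> pd.DataFrame:
    """Per-sample signal: filter at block level, then per-sample median.

    Background is estimated per (slide, block) from every spot's
    recorded background median, mirroring the lectin-array stage.
    Samples with zero surviving spots get ``median_signal`` NaN and
    ``no_signal`` True.
    """
    if "Group" not in spots.columns:
        raise PreprocessError("serum spot table is missing the 'Group' column")
    if "Sample" not in spots.columns:
        raise PreprocessError("serum spot table is missing the 'Sample' column")
    surviving = []
    bg_means = {}
    for (slide, block), sub in spots.groupby(["Slide", "Block"]):
        bg = block_background(sub)
        bg_means[(slide, block)] = bg.bg_mean
        surv = filter_effective_serum(sub, bg, k=k)
        surviving.append(surv)
    surv_all = pd.concat(surviving) if surviving else spots.iloc[0:0]

    rows = []
    for sample, sub in spots.groupby("Sample", sort=False):
        group = sub["Group"].iloc[0]
        mine = surv_all[surv_all["Sample"] == sample]
        if len(mine) == 0:
            rows.append({"sample": sample, "group": group, "median_signal": np.nan,
                         "n_effective": 0, "no_signal": True})
            continue
        # subtract each spot's own block background before pooling
        net = [
            max(row["F532 Median"] - bg_means[(row["Slide"], row["Block"])], 0.0)
            for _, row in mine.iterrows()
        ]
        rows.append(
            {
                "sample": sample,
                "group": group,
                "median_signal": float(np.median(net)),
                "n_effective": len(net),
                "no_signal": False,
            }
        )
    return pd.DataFrame(rows)


def group_compare(
    sample_signals: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> dict:
    """Group summaries, pairwise t p-values and ANOVA over sample medians.

    Returns a dict with

    - ``summary``: per-group ``n, mean, sd, q1, median, q3, ci95_lo,
      ci95_hi`` (95% CI of the mean from the t distribution — the error
      bars of a box-plot figure);
    - ``pairwise``: long table of two-sided t p-values per group pair;
    - ``anova_p``: one-way ANOVA p when > 2 usable groups.

    Groups with fewer than two usable samples are excluded (listed under
    ``excluded``).
    """
    usable = sample_signals[~sample_signals["no_signal"]]
    groups, excluded = {}, []
    # sorted by label so the export is independent of input row order
    for group, sub in usable.groupby("Group" if "Group" in usable.columns else "group"):
        vals = sub["median_signal"].to_numpy()
        if len(vals) < 2:
            excluded.append(group)
        else:
            groups[group] = vals
    if len(groups) < 2:
        raise PreprocessError("group comparison needs >= 2 groups with >= 2 samples")

    rows = []
    for group, vals in groups.items():
        n = len(vals)
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1) if n > 1 else np.nan
        half = tcrit * sd / np.sqrt(n)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "group": group, "n": n, "mean": mean, "sd": sd,
                "q1": float(q1), "median": float(med), "q3": float(q3),
                "ci95_lo": mean - half, "ci95_hi": mean + half,
            }
        )
    summary = pd.DataFrame(rows)

    labels = list(groups)
    pair_rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[j], labels[i]
            p = pairwise_t(groups[a], groups[b], equal_var=equal_var)
            fold = float(np.mean(groups[a]) / np.mean(groups[b])) if np.mean(groups[b]) else np.nan
            pair_rows.append({"pair": f"{a}/{b}", "group_a": a, "group_b": b,
                              "fold_change": fold, "p_value": p,
                              "significant": bool(p < alpha)})
    pairwise = pd.DataFrame(pair_rows)

    anova_p = multigroup_anova(list(groups.values())) if len(groups) > 2 else None
    return {"summary": summary, "pairwise": pairwise, "anova_p": anova_p, "excluded": excluded}


def concordance(lectin_calls: pd.DataFrame, serum_pairwise: dict[str, pd.DataFrame],
                alpha: float = 0.05) -> pd.DataFrame:
    """Direction agreement between lectin-array calls and serum validation.

    *serum_pairwise* maps lectin name to the ``pairwise`` table from
    :func:`group_compare` for the serum array probed with that lectin.
    The report is descriptive (per pair: lectin-array category, serum
    direction and significance, agreement flag); no inferential test is
    attached.
    """
    rows = []
    for lectin, pw in serum_pairwise.items():
        sub = lectin_calls[lectin_calls["lectin"] == lectin]
        for _, srow in pw.iterrows():
            match = sub[sub["pair"] == srow["pair"]]
            if match.empty:
                continue
            lcat = match["category"].iloc[0]
            sdir = "up" if srow["fold_change"] > 1 else "down"
            scat = sdir if srow["significant"] else "even"
            rows.append(
                {
                    "lectin": lectin,
                    "pair": srow["pair"],
                    "lectin_array_category": lcat,
                    "serum_array_category": scat,
                    "serum_fold": srow["fold_change"],
                    "serum_p": srow["p_value"],
                    "concordant": lcat == scat,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "lectin", "pair", "lectin_array_category", "serum_array_category",
            "serum_fold", "serum_p", "concordant",
        ],
    )
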