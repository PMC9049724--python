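"""Canned synthetic study designs and pipeline performance summaries.

These are the package's stand-ins for the original clinical experiment,
whose raw scanner data is not publicly deposited: a four-group
SCLC-style lectin-array design with planted fold effects, a null design
for type-I-error calibration, and the 30-samples-per-group reverse-phase
validation design.  Each function runs the *full* pipeline (simulate ->
filter -> normalize -> aggregate -> call) and measures how well the
planted truth is recovered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import Lectin, LectinPanel, SlideLayout, build_layout, default_panel
from .preprocess import aggregate_group, blocks_to_nfi
from .differential import Thresholds, call_set
from .serum_array import SerumSimConfig, group_compare, simulate_serum_array, summarize_samples
from .simulate import (
    GroupEffect,
    SimulationConfig,
    default_baseline,
    ground_truth_record,
    simulate_study,
)

__all__ = [
    "sclc_like_design",
    "run_simulated_study",
    "recovery_stats",
    "type1_error_rate",
    "serum_detection_power",
    "nfi_conservation_deviation",
]

#: Four pooled-serum groups mirroring the SCLC comparison arm, with five
#: planted fold effects (two-fold up or half down) spread over the
#: disease groups.
SCLC_LIKE_EFFECTS: dict[str, dict[str, float]] = {
    "HV": {},
    "BPD": {"EEL": 2.0},
    "LD-SCLC": {"BS-I": 2.0, "SNA": 0.5},
    "ED-SCLC": {"UEA-I": 2.0, "LEL": 0.5},
}


def sclc_like_design() -> list[GroupEffect]:
    return [GroupEffect(g, fm) for g, fm in SCLC_LIKE_EFFECTS.items()]


def run_simulated_study(
    groups: list[GroupEffect],
    seed: int,
    panel: LectinPanel | None = None,
    spot_cv: float = 0.10,
    dropout_rate: float = 0.01,
    thresholds: Thresholds = Thresholds(),
    layout: SlideLayout | None = None,
):
    """Simulate a study and run the lectin-array pipeline on it.

    Returns (call set, ground truth).  Three slides x three blocks per
    group, i.e. nine replicate blocks, as in the pooled-serum design.
    """
    if layout is None:
        layout = build_layout(panel or default_panel())
    config = SimulationConfig(
        baseline=default_baseline(layout.panel),
        spot_cv=spot_cv,
        dropout_rate=dropout_rate,
        seed=seed,
    )
    data, truth = simulate_study(groups, layout, config)
    nfis = {
        g: aggregate_group(g, blocks_to_nfi(tables, layout))
        for g, tables in data.items()
    }
    cs = call_set(nfis, [e.group for e in groups], thresholds=thresholds)
    return cs, truth


def recovery_stats(
    n_seeds: int = 20,
    seed: int = 0,
    spot_cv: float = 0.15,
    groups: dict[str, dict[str, float]] | None = None,
) -> dict:
    """Planted-effect recovery and false-positive load over seeds.

    Recovery: fraction of ground-truth (lectin, pair) effects called
    with the correct direction.  False positives: lectins called
    differential in a run although no effect was planted on them, mean
    per run.
    """
    effects = [GroupEffect(g, fm) for g, fm in (groups or SCLC_LIKE_EFFECTS).items()]
    panel = default_panel()
    layout = build_layout(panel)
    truth = ground_truth_record(effects, panel)
    truth_keys = set(zip(truth["lectin"], truth["pair"], truth["expected_category"]))
    planted_lectins = set(truth["lectin"])

    n_recovered = 0
    n_truth = 0
    fp_counts = []
    for i in range(n_seeds):
        cs, _ = run_simulated_study(
            effects, seed=seed + i, spot_cv=spot_cv, layout=layout
        )
        called = set(zip(cs.calls["lectin"], cs.calls["pair"], cs.calls["category"]))
        n_recovered += len(truth_keys & called)
        n_truth += len(truth_keys)
        fp_counts.append(len(cs.differential_lectins - planted_lectins))
    return {
        "recovery_rate": n_recovered / n_truth,
        "false_positive_lectins_per_run": float(np.mean(fp_counts)),
        "n_seeds": n_seeds,
        "n_planted_effects": len(truth_keys),
    }


def type1_error_rate(
    n_reps: int = 2000,
    seed: int = 0,
    n_lectins: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Per-lectin t-test rejection rate under a no-effect simulation.

    Two identical groups, nine replicate blocks each, full spot-level
    pipeline per replicate.  A compact panel keeps the replicate count
    high; the per-lectin rejection rate does not depend on panel size.
    """
    panel = LectinPanel(tuple(Lectin(f"L{i:02d}") for i in range(n_lectins)))
    layout = build_layout(panel)
    base = default_baseline(panel)
    n_rej = 0
    n_tests = 0
    for rep in range(n_reps):
        config = SimulationConfig(
            baseline=base, spot_cv=0.10, dropout_rate=0.0, seed=seed * n_reps + rep
        )
        data, _ = simulate_study(
            [GroupEffect("A"), GroupEffect("B")], layout, config
        )
        nfis = {
            g: aggregate_group(g, blocks_to_nfi(t, layout)) for g, t in data.items()
        }
        cs = call_set(nfis, ["A", "B"])
        p = cs.calls["p_value"]
        n_rej += int((p < alpha).sum())
        n_tests += int(p.notna().sum())
    return {"rejection_rate": n_rej / n_tests, "n_tests": n_tests, "n_reps": n_reps}


def serum_detection_power(
    n_seeds: int = 20,
    seed: int = 0,
    shift: float = 1.8,
    inter_cv: float = 0.3,
    n_samples: int = 30,
    alpha: float = 0.05,
) -> dict:
    """Detection rate of a planted group shift in the serum-array arm."""
    detected = 0
    for i in range(n_seeds):
        config = SerumSimConfig(
            group_means={"HV": 3000.0, "LC": 3000.0 * shift},
            n_samples=n_samples,
            inter_cv=inter_cv,
            seed=seed + i,
        )
        spots, _ = simulate_serum_array(config)
        comp = group_compare(summarize_samples(spots), alpha=alpha)
        p = comp["pairwise"]["p_value"].iloc[0]
        detected += int(p < alpha)
    return {"power": detected / n_seeds, "n_seeds": n_seeds}


def nfi_conservation_deviation(n_blocks: int = 1000, seed: int = 0) -> float:
    """Max |sum(effective NFIs) - 1| over randomized simulated blocks.

    Blocks draw random foregrounds, backgrounds and dropout flags, then
    run the background -> filter -> normalize chain.
    """
    from .preprocess import (
        DegenerateBlockError,
        block_background,
        filter_effective,
        lectin_block_nfi,
    )

    rng = np.random.default_rng(seed)
    panel = default_panel()
    worst = 0.0
    for _ in range(n_blocks):
        n_spots = panel.size * 3
        spots = pd.DataFrame(
            {
                "Block": 1,
                "Role": "lectin",
                "Name": np.repeat(panel.names, 3),
                "F532 Median": rng.uniform(0, 30000, n_spots),
                "B532 Median": rng.uniform(50, 400, n_spots),
                "Flags": np.where(rng.random(n_spots) < 0.02, -100, 0),
            }
        )
        bg = block_background(spots)
        surv = filter_effective(spots, bg, k=1.5)
        try:
            nfi, mask = lectin_block_nfi(surv, panel, bg)
        except DegenerateBlockError:
            continue
        worst = max(worst, abs(float(nfi[mask].sum()) - 1.0))
    return worst
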