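"""Synthetic lectin-microarray slide generator with known ground truth.

The study design being emulated: pooled serum per subject group, each
pool hybridized to three replicate slides of three blocks each, so every
group contributes nine replicate blocks.  Raw scanner data for the
original study is not deposited, so this generator is the test bed for
the whole pipeline — it writes the same spot-table dialect the reader
consumes and records exactly which (lectin, group pair) effects were
planted.

Noise model
-----------
Spot foreground = ``baseline[lectin] x fold x LN(1, cv) + B`` where
``LN(1, cv)`` is a lognormal factor with mean 1 and coefficient of
variation ``spot_cv`` (multiplicative noise is the standard model for
fluorescence spot intensities) and ``B`` is an additive background draw
from ``Normal(background_mean, background_sd)`` truncated at zero.  The
recorded background median is an independent draw from the same
background distribution.  Negative-control spots carry background-only
foreground; markers a high fixed intensity.  Dropout flags spots with a
negative value following the GenePix convention.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import ROLE_LECTIN, ROLE_MARKER, ROLE_NEGATIVE, LectinPanel, SlideLayout

__all__ = [
    "GroupEffect",
    "SimulationConfig",
    "SimulationError",
    "default_baseline",
    "simulate_group",
    "simulate_study",
    "ground_truth_record",
    "SPOT_COLUMNS",
]

SPOT_COLUMNS = [
    "Slide",
    "Block",
    "Row",
    "Column",
    "Role",
    "Name",
    "F532 Median",
    "B532 Median",
    "Flags",
]

DROPOUT_FLAG = -100


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GroupEffect:
    """Ground-truth multiplicative fold effects for one subject group."""

    group: str
    fold_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.fold_map.items() if not v > 0}
        if bad:
            raise SimulationError(f"folds must be > 0, got {bad}")

    def fold(self, lectin: str) -> float:
        return self.fold_map.get(lectin, 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study structure: 3 slides per pooled group
    (x 3 blocks per slide = 9 replicate blocks), 10% spot-level CV,
    background around 300 fluorescence units with SD 30 (typical Cy3
    scanner floor), 1% spot dropout.
    """

    baseline: dict[str, float]
    spot_cv: float = 0.10
    background_mean: float = 300.0
    background_sd: float = 30.0
    dropout_rate: float = 0.01
    n_slides: int = 3
    seed: int = 0
    marker_intensity: float = 50000.0

    def __post_init__(self) -> None:
        if self.spot_cv < 0 or self.background_sd < 0:
            raise SimulationError("spot_cv and background_sd must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise SimulationError("dropout_rate must be in [0, 1)")
        if any(v <= 0 for v in self.baseline.values()):
            raise SimulationError("baseline intensities must be > 0")


def default_baseline(panel: LectinPanel, low: float = 800.0, high: float = 24000.0) -> dict[str, float]:
    """Deterministic baseline intensities spread geometrically over the panel.

    Real panels span more than an order of magnitude in signal; a fixed
    geometric spread in panel order reproduces that spread reproducibly
    without a random draw.
    """
    n = panel.size
    if n == 1:
        return {panel.names[0]: low}
    ratio = (high / low) ** (1.0 / (n - 1))
    return {name: low * ratio**i for i, name in enumerate(panel.names)}


def _sub_seed(master: int, group: str, slide: int) -> np.random.Generator:
    # crc32 keeps sub-seeds stable across processes (unlike hash())
    tag = zlib.crc32(f"{group}/{slide}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([master & 0x7FFFFFFF, tag]))


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Lognormal multiplier with mean 1 and coefficient of variation *cv*."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    mu = -0.5 * sigma2
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def _background(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(mean))
    return np.clip(rng.normal(mean, sd, size=size), 0.0, None)


def simulate_group(
    layout: SlideLayout,
    effect: GroupEffect,
    config: SimulationConfig,
) -> list[pd.DataFrame]:
    """Simulate all replicate slides for one pooled group.

    Returns one spot table per slide (``n_slides`` tables) with columns
    :data:`SPOT_COLUMNS`.  Deterministic for a fixed config seed: each
    (group, slide) pair draws from its own derived sub-stream, so adding
    a group never perturbs another group's data.
    """
    missing = [
        name
        for (_, _, _), (role, name) in layout.grid_map.items()
        if role == ROLE_LECTIN and name not in config.baseline
    ]
    if missing:
        raise SimulationError(f"no baseline for lectins: {sorted(set(missing))}")

    coords = sorted(layout.grid_map)
    roles = np.array([layout.grid_map[c][0] for c in coords])
    names = np.array([layout.grid_map[c][1] for c in coords])
    blocks = np.array([c[0] for c in coords])
    rows = np.array([c[1] for c in coords])
    cols = np.array([c[2] for c in coords])
    n = len(coords)

    true_level = np.zeros(n)
    is_lectin = roles == ROLE_LECTIN
    for name in np.unique(names[is_lectin]):
        sel = is_lectin & (names == name)
        true_level[sel] = config.baseline[name] * effect.fold(name)
    true_level[roles == ROLE_MARKER] = config.marker_intensity

    tables = []
    for slide in range(1, config.n_slides + 1):
        rng = _sub_seed(config.seed, effect.group, slide)
        noise = _lognormal_factor(rng, config.spot_cv, n)
        fg_bg = _background(rng, config.background_mean, config.background_sd, n)
        foreground = true_level * noise + fg_bg
        # negative controls: background-only signal
        neg = roles == ROLE_NEGATIVE
        foreground[neg] = fg_bg[neg]
        background = _background(rng, config.background_mean, config.background_sd, n)
        flags = np.zeros(n, dtype=int)
        if config.dropout_rate > 0:
            flags[rng.random(n) < config.dropout_rate] = DROPOUT_FLAG
        tables.append(
            pd.DataFrame(
                {
                    "Slide": slide,
                    "Block": blocks,
                    "Row": rows,
                    "Column": cols,
                    "Role": roles,
                    "Name": names,
                    "F532 Median": foreground,
                    "B532 Median": background,
                    "Flags": flags,
                }
            )
        )
    return tables


def ground_truth_record(
    groups: list[GroupEffect],
    panel: LectinPanel,
    up_threshold: float = 1.5,
    down_threshold: float = 0.67,
) -> pd.DataFrame:
    """Every (lectin, group pair) whose true relative fold crosses a threshold.

    Pairs follow the design order: for groups listed ``[g1, g2, ...]``
    the pair label ``"g2/g1"`` carries fold ``fold_g2 / fold_g1``.
    Independent of any random seed by construction.
    """
    records = []
    effects = {e.group: e for e in groups}
    labels = [e.group for e in groups]
    for j in range(1, len(labels)):
        for i in range(j):
            a, b = labels[j], labels[i]
            for name in panel.names:
                fold = effects[a].fold(name) / effects[b].fold(name)
                if fold >= up_threshold or fold <= down_threshold:
                    records.append(
                        {
                            "lectin": name,
                            "pair": f"{a}/{b}",
                            "true_fold": fold,
                            "expected_category": "up" if fold >= up_threshold else "down",
                        }
                    )
    return pd.DataFrame(records, columns=["lectin", "pair", "true_fold", "expected_category"])


def simulate_study(
    groups: list[GroupEffect],
    layout: SlideLayout,
    config: SimulationConfig,
) -> tuple[dict[str, list[pd.DataFrame]], pd.DataFrame]:
    """Simulate every group of a study design.

    Returns (mapping group -> list of per-slide spot tables, ground-truth
    record of planted differential effects).
    """
    labels = [e.group for e in groups]
    if len(set(labels)) != len(labels):
        raise SimulationError(f"duplicate group labels in {labels}")
    data = {e.group: simulate_group(layout, e, config) for e in groups}
    truth = ground_truth_record(groups, layout.panel)
    return data, truth
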