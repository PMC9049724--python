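"""End-to-end orchestration: panel -> (simulate | read) -> NFI ->
differential -> cluster, plus the serum validation arm.

A single :class:`RunConfig` surfaces every analysis constant (filter
multipliers k = 1.5 / 2.0, fold thresholds 1.5 / 0.67, alpha = 0.05,
test and correction options, clustering options, seed); nothing is
hard-coded inside the stages.  Each run writes a manifest recording the
full configuration so a rerun with the same seed reproduces every output
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .panel import LectinPanel, SlideLayout, build_layout, default_panel, load_panel
from .array_io import read_spot_table, write_spot_table
from .preprocess import GroupNFI, aggregate_group, blocks_to_nfi
from .differential import CallSet, Thresholds, call_set, cross_type, table2_style
from .cluster import hcluster, plot_heatmap
from .simulate import GroupEffect, SimulationConfig, default_baseline, simulate_study
from .serum_array import SerumSimConfig, group_compare, simulate_serum_array, summarize_samples

log = logging.getLogger("lectinarray")

__all__ = ["RunConfig", "ConfigError", "run_lectin_arm", "run_serum_arm", "run_cross_type"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All knobs of a pipeline run, defaulted to the study's values."""

    groups: dict[str, dict[str, float]] = field(default_factory=dict)  # group -> fold_map
    panel_path: str | None = None
    blocks_per_slide: int = 3
    spots_per_lectin: int = 3
    n_slides: int = 3
    spot_cv: float = 0.10
    background_mean: float = 300.0
    background_sd: float = 30.0
    dropout_rate: float = 0.01
    k_filter: float = 1.5
    k_serum: float = 2.0
    up_threshold: float = 1.5
    down_threshold: float = 0.67
    alpha: float = 0.05
    equal_var: bool = True
    correction: str | None = None
    cluster_distance: str = "correlation"
    cluster_linkage: str = "average"
    write_heatmap: bool = False
    serum_group_means: dict[str, float] = field(default_factory=dict)
    serum_n_samples: int = 30
    serum_inter_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.down_threshold < 1 < self.up_threshold:
            raise ConfigError("need down_threshold < 1 < up_threshold")
        if self.k_filter < 0 or self.k_serum < 0:
            raise ConfigError("filter multipliers must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def thresholds(self) -> Thresholds:
        return Thresholds(up=self.up_threshold, down=self.down_threshold, alpha=self.alpha)

    def panel(self) -> LectinPanel:
        return load_panel(self.panel_path) if self.panel_path else default_panel()

    def layout(self) -> SlideLayout:
        return build_layout(self.panel(), self.blocks_per_slide, self.spots_per_lectin)


def _manifest(config: RunConfig, outdir: Path, extra: dict) -> None:
    payload = {
        "software": "lectinarray",
        "version": __version__,
        "config": dataclasses.asdict(config),
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


def _simulate_or_read(config: RunConfig, layout, input_tables: dict | None):
    if input_tables is not None:
        data = {
            g: [read_spot_table(p, layout) for p in paths]
            for g, paths in input_tables.items()
        }
        truth = None
    else:
        if not config.groups:
            raise ConfigError("no groups configured and no input tables given")
        effects = [GroupEffect(group=g, fold_map=fm or {}) for g, fm in config.groups.items()]
        sim = SimulationConfig(
            baseline=default_baseline(layout.panel),
            spot_cv=config.spot_cv,
            background_mean=config.background_mean,
            background_sd=config.background_sd,
            dropout_rate=config.dropout_rate,
            n_slides=config.n_slides,
            seed=config.seed,
        )
        data, truth = simulate_study(effects, layout, sim)
    return data, truth


def run_lectin_arm(
    config: RunConfig,
    outdir: str | Path,
    input_tables: dict[str, list] | None = None,
) -> dict:
    """Run the lectin-array arm end to end and write all outputs.

    Uses simulated data from ``config.groups`` unless *input_tables*
    maps group labels to lists of spot-table paths.  Writes per-group
    NFI tables, ``group_nfi.tsv``, ``calls.tsv``, ``table2_style.tsv``,
    Newick dendrograms and a manifest under *outdir*.  Returns the
    in-memory results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = config.layout()
    data, truth = _simulate_or_read(config, layout, input_tables)

    group_nfis: dict[str, GroupNFI] = {}
    nfi_cols = {}
    n_spots = 0
    for group, tables in data.items():
        n_spots += sum(len(t) for t in tables)
        nfi = blocks_to_nfi(tables, layout, k=config.k_filter)
        group_nfis[group] = aggregate_group(group, nfi)
        for col in nfi.values.columns:
            nfi_cols[f"{group}:{col}"] = nfi.values[col]
        log.info("group %s: %d blocks, %d lectins effective in all blocks",
                 group, nfi.values.shape[1], int(nfi.mask.all(axis=1).sum()))
    nfi_table = pd.DataFrame(nfi_cols)
    nfi_table.index.name = "lectin"

    summary = pd.concat(
        [g.summary.assign(group=name).reset_index() for name, g in group_nfis.items()]
    )[["group", "lectin", "mean_nfi", "sd", "n_blocks"]]

    design = list(data)
    calls = call_set(
        group_nfis, design,
        thresholds=config.thresholds(),
        equal_var=config.equal_var,
        correction=config.correction,
    )
    log.info("differential lectins: %d of %d", len(calls.differential_lectins), layout.panel.size)

    clust = hcluster(
        nfi_table.fillna(0.0),
        distance=config.cluster_distance,
        linkage=config.cluster_linkage,
    )

    nfi_table.to_csv(outdir / "nfi_blocks.tsv", sep="\t")
    summary.to_csv(outdir / "group_nfi.tsv", sep="\t", index=False)
    calls.calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    table2_style(calls).to_csv(outdir / "table2_style.tsv", sep="\t")
    (outdir / "rows.nwk").write_text(clust.row_newick())
    if clust.col_linkage is not None:
        (outdir / "cols.nwk").write_text(clust.col_newick())
    clust.ordered.to_csv(outdir / "heatmap_matrix.tsv", sep="\t")
    if config.write_heatmap:
        plot_heatmap(clust, outdir / "heatmap.png")
    if truth is not None:
        truth.to_csv(outdir / "ground_truth.csv", index=False)
    if input_tables is None:
        raw_dir = outdir / "spots"
        raw_dir.mkdir(exist_ok=True)
        for group, tables in data.items():
            for i, t in enumerate(tables, start=1):
                write_spot_table(t, raw_dir / f"{group}_slide{i}.tsv")
    _manifest(config, outdir, {
        "arm": "lectin",
        "n_lectins": layout.panel.size,
        "n_spots_read": n_spots,
        "groups": design,
        "blocks_per_group": {g: int(group_nfis[g].blocks.shape[1]) for g in design},
        "n_differential_lectins": len(calls.differential_lectins),
        "test_metadata": calls.metadata,
    })
    return {
        "layout": layout,
        "group_nfis": group_nfis,
        "nfi_table": nfi_table,
        "calls": calls,
        "cluster": clust,
        "ground_truth": truth,
    }


def run_serum_arm(config: RunConfig, outdir: str | Path,
                  spots: pd.DataFrame | None = None) -> dict:
    """Run the reverse-phase serum arm: simulate (or take) spots,
    filter at k = 2, summarize per sample, compare groups, export
    box-plot statistics and a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = None
    if spots is None:
        if not config.serum_group_means:
            raise ConfigError("serum_group_means is empty and no spot table was given")
        sim = SerumSimConfig(
            group_means=config.serum_group_means,
            n_samples=config.serum_n_samples,
            inter_cv=config.serum_inter_cv,
            spot_cv=config.spot_cv,
            background_mean=config.background_mean,
            background_sd=config.background_sd,
            dropout_rate=config.dropout_rate,
            seed=config.seed,
        )
        spots, truth = simulate_serum_array(sim)
    signals = summarize_samples(spots, k=config.k_serum)
    comp = group_compare(signals, alpha=config.alpha, equal_var=config.equal_var)
    log.info("serum arm: %d samples, %d no-signal, ANOVA p=%s",
             len(signals), int(signals["no_signal"].sum()), comp["anova_p"])

    signals.to_csv(outdir / "sample_signals.tsv", sep="\t", index=False)
    comp["summary"].to_csv(outdir / "boxplot_stats.csv", index=False)
    comp["pairwise"].to_csv(outdir / "serum_pairwise.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_csv(outdir / "serum_ground_truth.csv", index=False)
    _manifest(config, outdir, {
        "arm": "serum",
        "n_samples": len(signals),
        "n_no_signal": int(signals["no_signal"].sum()),
        "anova_p": comp["anova_p"],
        "excluded_groups": comp["excluded"],
    })
    return {"spots": spots, "signals": signals, "comparison": comp, "ground_truth": truth}


def run_cross_type(type_results: dict[str, dict], config: RunConfig,
                   outdir: str | Path) -> pd.DataFrame:
    """Cross-cancer-type comparison over per-type lectin-arm results.

    *type_results* maps type label to the dict returned by
    :func:`run_lectin_arm`; the type-level NFI is taken from the cancer
    groups of each design (every group except HV/BPD controls, pooled
    block-wise).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    type_nfis = {}
    for label, res in type_results.items():
        cancer = {g: nfi for g, nfi in res["group_nfis"].items() if g not in ("HV", "BPD")}
        if not cancer:
            raise ConfigError(f"type {label}: no cancer groups to pool")
        blocks = pd.concat(
            [nfi.blocks.add_prefix(f"{g}:") for g, nfi in cancer.items()], axis=1
        )
        n_blocks = blocks.notna().sum(axis=1).astype(int)
        summary = pd.DataFrame({
            "mean_nfi": blocks.mean(axis=1),
            "sd": blocks.std(axis=1, ddof=1),
            "n_blocks": n_blocks,
            "usable": n_blocks >= 2,
        })
        type_nfis[label] = GroupNFI(group=label, blocks=blocks, summary=summary)
    report = cross_type(type_nfis, thresholds=config.thresholds(), equal_var=config.equal_var)
    report.to_csv(outdir / "cross_type.tsv", sep="\t")
    return report
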