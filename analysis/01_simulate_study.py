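#!/usr/bin/env python
"""Simulate the four-group pooled-serum lectin-array study.

Generates scanner-style spot tables for HV, BPD, LD-SCLC and ED-SCLC
pools (three slides x three blocks each, 37-lectin panel, five planted
fold effects) and writes them, with the ground-truth effect record, to
results/simulated/.
"""

from pathlib import Path

from lectinarray.array_io import write_spot_table
from lectinarray.panel import build_layout, default_panel, write_layout
from lectinarray.simulate import GroupEffect, SimulationConfig, default_baseline, simulate_study
from lectinarray.studies import SCLC_LIKE_EFFECTS

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 20260927


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = default_panel()
    layout = build_layout(panel)
    write_layout(layout, OUT / "layout.csv")
    config = SimulationConfig(baseline=default_baseline(panel), seed=SEED)
    groups = [GroupEffect(g, fm) for g, fm in SCLC_LIKE_EFFECTS.items()]
    data, truth = simulate_study(groups, layout, config)
    n = 0
    for group, tables in data.items():
        for i, table in enumerate(tables, start=1):
            write_spot_table(table, OUT / f"{group}_slide{i}.tsv")
            n += 1
    truth.to_csv(OUT / "ground_truth.csv", index=False)
    print(f"wrote {n} slide tables ({len(groups)} groups x {config.n_slides} slides) to {OUT}")
    print(f"planted differential effects ({len(truth)} lectin-pair entries):")
    print(truth.to_string(index=False))


if __name__ == "__main__":
    main()
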