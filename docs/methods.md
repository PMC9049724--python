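# Methods

## Measurement model

A lectin-array slide carries `B` identical blocks; each block holds the
full lectin panel spotted `r` times (defaults `B = 3`, `r = 3`) plus
Cy3-BSA location markers and BSA negative controls. A pooled serum
sample is hybridized to three replicate slides, so each group
contributes `3 × B = 9` replicate blocks — the replication unit for all
group statistics. (Sources disagree on whether slides carry three or
four blocks per slide; three is used so that 3 slides × 3 blocks matches
the 9 replicate blocks the statistics are computed over, and the count
is configurable.)

Per spot the scanner reports a foreground and a background median
(532 nm, Cy3). The analysis chain is:

- **Block background** — mean ± SD of the background medians of all
  spots in the block. The phrase "average background" is read at block
  level, with controls included by default (a lectin-spots-only mode is
  provided, since the original description does not say which was used).
- **Effective data points** — spots with non-negative QC flag whose
  foreground is at least `bg_mean + k·bg_SD` (`k = 1.5` lectin arrays,
  `k = 2.0` serum arrays; threshold inclusive). The removal rule
  "values less than the average background ± k SD" is directionally
  ambiguous; the detection-limit reading (signal must clear background
  noise upward) is the default, and the literal lower-bound reading
  (`bg_mean − k·bg_SD`) is selectable for sensitivity analysis.
- **NFI** — per lectin, the median of effective background-subtracted
  foregrounds (subtraction floored at 0; median of an even count is the
  central midpoint), divided by the sum of medians over all effective
  lectins in the block. NFIs are kept as fractions (block sum exactly
  1); any ×100 presentation is display-only. A lectin with no effective
  spot in a block is non-effective there; a block whose sum of medians
  is zero is degenerate and aborts with a named error.
- **Aggregation** — per lectin, mean and sample SD (ddof = 1) of NFIs
  over the blocks where it was effective; lectins effective in fewer
  than two blocks are unusable for testing and reported as
  `not_comparable`.

## Differential calling

For each ordered pair in the design (later group over earlier, so a
design `[HV, BPD, …]` yields pairs `BPD/HV`, …): fold change is the
ratio of mean NFIs and significance a two-sided pooled-variance
Student's t over replicate blocks (Welch optional; variance handling is
not specified in the original description). Categories: **up** iff
fold ≥ 1.5 and p < 0.05; **down** iff fold ≤ 0.67 and p < 0.05; else
**even**. Both fold boundaries are inclusive; α is strict. The
published down threshold 0.67 is not exactly 1/1.5, so up/down are not
exactly reciprocal under the defaults — the antisymmetry
`category(a,b)=up ⟺ category(b,a)=down` holds only under a
`down = 1/up` configuration and is asserted in tests only there.

No multiple-testing correction is applied by default, matching the
original 37-lectin analysis; a Benjamini–Hochberg flag is available and
recorded in output metadata. With more than two groups a one-way ANOVA
p-value is attached per lectin but does not gate the pairwise
categories (the original reports both tests without stating a gate).
Degenerate inputs resolve by limit: identical zero-variance samples
give p = 1, zero-variance samples with different means p = 0.

**Cross-type comparison.** Type-level NFI replicates (cancer groups
pooled block-wise, controls excluded) are compared pairwise with the
same machinery. Each lectin is classified by the minority type: if one
type differs in the same direction from all others while the others are
mutually even, the pattern is `increased/decreased_in_T_vs_rest`; the
report also carries the logically equivalent majority phrasing
(`increased_in_A+B_vs_C`) in a `dual` column, since the two readings
cannot be distinguished from the data. Anything else is `mixed`.

**Summary-statistics path.** `calls_from_summary` applies the same
criteria to a `group, lectin, mean_nfi, sd, n_blocks` table via
t-from-summary-statistics, for re-analyzing published mean ± SD NFI
tables where raw replicates are unavailable; with matching inputs it
reproduces the raw-replicate calls exactly (tested).

## Clustering

Rows (lectins) are standardized to mean 0 / sample SD 1 (constant rows
become zeros), then rows and columns are clustered agglomeratively.
Defaults: Pearson-correlation distance (1 − r) with average linkage —
the customary configuration of expression-heatmap tools; both are
configurable and recorded in the result. Correlation with a
zero-variance row is undefined; such distances are set to 1
(uninformative). Dendrograms export as Newick with branch lengths that
reproduce merge heights; published dendrogram topology is not an
acceptance surface because the original tool's settings are unstated.

## Serum validation arm

Reverse-phase format: individual samples spotted in triplicate per
block, two blocks per slide (six replicate spots per sample), probed
with one labeled lectin. Per sample: spots filtered at `k = 2` against
their block background (the identical filter implementation as the
lectin arm — asserted equal at equal k), median of effective net
foregrounds; samples with no effective spot are flagged no-signal and
excluded. Groups are compared on sample medians (t / ANOVA); the
box-plot export carries quartiles and the 95% CI of the mean from the
t distribution. A descriptive concordance report links lectin-array
call directions to serum-array outcomes per lectin and pair; no
inferential test is attached to concordance.

## Synthetic data

The simulator stands in for undeposited raw scanner data; its defaults
are the study conditions, not tuning knobs.

| parameter | default | meaning |
|---|---|---|
| baseline | geometric spread 800–24 000 AU over the panel | per-lectin true spot intensity; real panels span >1 order of magnitude |
| spot_cv | 0.10 | CV of multiplicative lognormal spot noise (mean-1 factor) |
| background_mean / sd | 300 / 30 AU | additive Gaussian background, truncated at 0 |
| dropout_rate | 0.01 | per-spot probability of a negative QC flag |
| n_slides | 3 | replicate slides per pooled group (×3 blocks = 9) |
| marker_intensity | 50 000 AU | fixed Cy3-BSA marker level |
| serum inter_cv | 0.3 | inter-individual lognormal CV in the serum arm |
| serum n_samples | 30 | individuals per group, as in the validation design |

Spot foreground = `baseline × fold × LN(1, cv) + background draw`; the
recorded background median is an independent draw from the same
distribution, so in the noiseless limit pipeline NFIs equal the
closed-form `baseline × fold` fractions exactly (oracle-equivalence
test). Multiplicative lognormal noise is the standard model for
fluorescence spot intensities; no noise model is stated in the original
description, so this is the simulator's own documented stand-in.
Sub-seeds per (group, slide) derive from the master seed via CRC32 of
the labels, so adding a group never perturbs existing groups' data and
runs are reproducible across processes.

Not emulated: spatial artifacts (gradients, scratches), dye bias,
inter-slide batch effects beyond independent noise, and — in the
lectin-array arm — individual-donor variation (pools are modeled
directly; individual variation appears only in the serum arm). Passing
tests therefore demonstrate correctness and calibration of the analysis
chain under well-behaved noise, not robustness to systematic artifacts
of real slides.

Note one structural consequence of sum normalization: planting a ×2
effect on a lectin carrying ~7% of the block signal yields an observed
NFI fold of ≈ 2/1.07 ≈ 1.87, and all other lectins are weakly pushed
down. Recovery checks account for this compression; it is a property of
the normalization, not an estimator defect.

## Calibration and power checks (problem sizes)

The study-condition checks run at sizes chosen to keep the full suite
in minutes on one CPU: NFI conservation over 1000 randomized blocks;
type-I error over 2000 null replicates of the full spot-level pipeline
on a compact 10-lectin panel (the per-lectin rejection rate is a
marginal property and does not depend on panel size), expected
0.05 ± 0.02; planted-effect recovery on the four-group, five-effect
design at spot CV 0.15 over 20 seeds (≥ 95% recovery, < 2 false-positive
lectins per run); serum-arm power at 30 samples/group, 1.8× shift,
CV 0.3 over 20 seeds (≥ 95%). The t test is checked against a
10⁵-resample permutation oracle on 50 random samples of 10–20
replicates per side with an a-priori bound of 0.02 per case: the Monte
Carlo SE is ≈ 7×10⁻⁴ and the finite-sample t-vs-permutation discrepancy
is O(1/n) ≈ 0.01 at these sizes; two-group ANOVA must satisfy F = t² to
1e-9.

## Known limitations

- The original clinical findings rest on pooled sera that are not
  publicly deposited; the pipeline's correctness is therefore
  established on synthetic ground truth, and published lectin counts
  are not a desk-side acceptance surface. The summary-statistics path
  exists precisely so published mean ± SD tables can be re-analyzed
  when available.
- Fold compression under sum normalization (above) biases fold
  estimates of high-abundance lectins toward 1; the calling thresholds
  are applied to the compressed (observed) folds, as in the original
  analysis.
- The pooled-variance t test on 9 compositional replicates is used as
  specified; NFIs of different lectins within a block are not
  independent (they sum to 1), which leaves per-lectin marginal tests
  calibrated (verified) but makes joint inferences across lectins
  conservative or anti-conservative in ways the original design does
  not address.
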