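# lectinarray

Analysis pipeline for **serum protein glycopattern profiling with lectin
microarrays**, built for studies that compare pooled patient sera across
disease groups — e.g. healthy volunteers (HV), benign pulmonary disease
(BPD) and lung-cancer subtypes (SCLC, ADC, SqCC) — and validate candidate
lectins on reverse-phase serum arrays of individual samples.

## What it computes

A lectin microarray spots a panel of 37 carbohydrate-binding proteins
(lectins) in triplicate within each block of a slide; Cy3-labeled pooled
serum proteins are hybridized, and each lectin's fluorescence reports the
abundance of its glycan epitope. The pipeline implements the standard
analysis chain:

1. **Background filtering.** Per block, the background level is the mean
   ± SD of all spots' background medians. Spots whose foreground fails to
   clear `bg_mean + k·bg_SD` are removed (k = 1.5 for lectin arrays,
   k = 2 for serum arrays); survivors are the *effective data points*.
2. **Sum-of-medians normalization.** Per lectin, the median of its
   effective background-subtracted foregrounds is divided by the sum of
   medians over all effective lectins in the block, giving the
   **Normalized Fluorescence Intensity** (NFI), a fraction with
   `Σ_lectins NFI = 1` per block.
3. **Replicate aggregation.** Each pooled group is measured on 3 slides ×
   3 blocks = 9 replicate blocks; per lectin the NFI mean ± SD over
   blocks is reported.
4. **Differential calling.** For each group pair, fold change =
   NFĪₐ/NFĪ_b with a two-sided Student's t test over replicate blocks:
   **up** if fold ≥ 1.5 and p < 0.05, **down** if fold ≤ 0.67 and
   p < 0.05, otherwise **even**; one-way ANOVA accompanies >2-group
   designs. A cross-cancer-type report classifies each lectin's pattern
   (e.g. "increased in ADC and SqCC vs SCLC").
5. **Clustering.** Row-standardized NFI profiles are clustered
   agglomeratively (Pearson-correlation distance, average linkage) for
   the red/black/green heatmap view; dendrograms export as Newick.
6. **Serum-array validation.** Individual samples spotted in triplicate ×
   two blocks, probed with one labeled lectin: per-sample median of
   effective spots, then group mean ± SD, 95% CIs and t/ANOVA tests.

Because raw scanner data for such studies is rarely deposited, the
package includes a **synthetic-slide simulator** with planted
multiplicative fold effects and a ground-truth record, so the whole chain
is testable end to end (filter calibration, type-I error, power,
false-positive load).

## Worked example

The numbered drivers under `analysis/` run a complete simulated study
(four pooled groups, five planted effects — EEL ×2 in BPD; BS-I ×2 and
SNA ×0.5 in LD-SCLC; UEA-I ×2 and LEL ×0.5 in ED-SCLC):

```sh
python analysis/01_simulate_study.py   # scanner-style spot tables + ground truth
python analysis/02_lectin_arm.py       # filter -> NFI -> calls -> clustering
python analysis/03_cross_type.py       # SCLC/ADC/SqCC pattern classification
python analysis/04_serum_validation.py # reverse-phase serum arm, n = 30/group
```

`02_lectin_arm.py` prints:

```
differential lectins called: ['BS-I', 'EEL', 'LEL', 'SNA', 'UEA-I']
planted lectins:             ['BS-I', 'EEL', 'LEL', 'SNA', 'UEA-I']
recovered 5/5, false positives: none
```

i.e. every planted effect is recovered with no spurious lectins: the
`calls.tsv` table lists, per lectin and group pair, the fold change,
p-value and category, and `table2_style.tsv` renders the familiar
fold+arrow matrix (`1.841↑` for EEL BPD/HV in this run — the estimate
sits below the planted 2.0 because sum normalization compresses large
single-lectin effects; see `docs/methods.md`). `04_serum_validation.py`
ends with the group table

```
  group  n   mean     sd  ...  ci95_lo  ci95_hi
LD-SCLC 30 5360.3 1721.3  ...   4717.5   6003.0
```

and pairwise tests in which the planted 1.8× SCLC shifts are detected at
p < 1e-8 while HV vs BPD (no planted shift) stays non-significant.

A `lectinarray` CLI (`simulate`, `lectin-run`, `serum-run`, `cross-type`)
exposes the same pipeline with a YAML config.

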