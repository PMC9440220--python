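# Methods

This note documents the statistical procedures implemented in `gnotodiff`,
the model behind its synthetic-data generator, the defaults and why they
were chosen, and the numerical conventions adopted where the underlying
analysis recipe leaves choices open.

## The analysis procedure

The unit of analysis is one molecular feature (an aligned LC–MS peak in one
analytical mode) within one tissue, compared between germ-free (GF) and
conventionally-raised (MPF) mice with five replicates per group. Per-mode
feature tables are concatenated into one matrix before any statistics, with
feature ids namespaced `mode:id` to keep the merged index unique (the
concatenation convention is ours; collisions across modes are otherwise
possible).

### False-zero imputation

Imputation runs first, independently for every (feature, tissue, group)
replicate vector, and the imputed matrix is the only matrix any later stage
sees. The decision procedure uses two thresholds: a zero-fraction cut
(default 0.60) and a raw-intensity cut (default 10,000 counts, an
instrument-scale convention rather than a fitted quantity):

| condition | action | reading |
| --- | --- | --- |
| zero fraction > 60% | all values → 0 | zeros are real; stray detections discarded (rule 1) |
| zero fraction < 60%, non-zero values below 10,000 | all values → 0 | too faint to trust (rule 2) |
| zero fraction < 60%, non-zero values above 10,000 | zeros → mean of non-zero replicates | zeros are dropout (rule 3) |
| no zeros | unchanged | nothing to decide |

Two cases the rule set leaves open are explicit policy fields:

- **Exact 60% boundary** (3 zeros of 5): routed to rule 1 by default — the
  conservative choice for presence calling, since it never manufactures a
  detection. Configurable (`boundary_rule="rule3_branch"`).
- **Non-zero values straddling 10,000**: decided by comparing the *mean* of
  the non-zero values to the threshold (`mixed_rule="mean"`), which is
  self-consistent in that the quantity compared is exactly the value rule 3
  would impute. `all_above` / `any_above` variants are provided.

Useful consequences, verified by property tests: after imputation each group
vector is either all-zero or all-positive; the procedure is idempotent;
rules 1–2 never create non-zero values and rule 3 never creates zeros; the
rule-3 fill value is the exact arithmetic mean (no tolerance on rational
inputs).

### Differential testing

Fold change is FC = mean(GF)/mean(MPF) on the imputed replicate means, so
FC > 1 means higher in GF. When one group's mean is zero the record carries
a `gf_only`/`mpf_only` flag instead of an infinite ratio; a finite-FC mode
(`zero_handling="floor"`, numerator or denominator replaced by ε = 1 count)
exists for displays that need coordinates for every point.

The two-sided Mann–Whitney p value is computed by complete enumeration of
all C(10, 5) = 252 group labelings of the pooled mid-ranks: p is the
fraction of labelings whose rank sum deviates from the null mean at least
as much as the observed one. Rationale: at n = 5 + 5 the normal
approximation is poorly calibrated, enumeration is cheap, and mid-ranks
inside the enumeration handle ties exactly (the null conditions on the
observed tie pattern). The smallest attainable tie-free p is 2/252 ≈
0.0079 — a hard floor that matters downstream (see "BH discreteness").

Benjamini–Hochberg adjustment is applied per tissue over that tissue's
tested features (features absent from both groups are excluded from the
test and the correction batch — they carry no data and would only dilute
the adjustment). Group-exclusive features *are* tested (their imputed
vector is zeros vs non-zeros, yielding p = 2/252 at full separation) so
they can be counted among significant features. The BH computation itself
is delegated to `statsmodels.stats.multitest.multipletests`; tests verify
it against a direct evaluation of the step-up formula.

### Significance calling and accounting

The inclusion filter is a conjunction: FC ≥ 1.3 **in either direction**
(fc ≥ 1.3 or fc ≤ 1/1.3; exclusivity counts as passing), p ≤ 0.05,
q ≤ 0.05, maximum raw abundance across the tissue's ten samples ≥ 100,000,
MS/MS spectrum present, retention time ≥ 0.7 min. The two-sided FC reading
is deliberate: direction-of-change summaries report metabolites higher in
*either* group, which a one-sided reading could not produce. A literal
one-sided mode is available (`two_sided=False`).

Volcano classification highlights a feature iff q < 0.1 and its FC falls
outside its tissue class's window — (0.005, 200) for the large intestine
(cecum, colon), (0.01, 100) for the small intestine (duodenum, jejunum,
ileum), (0.033, 30) elsewhere — reflecting the much wider fold-change range
observed in gut tissue. Exclusive features are placed at the plot extremes
by capping FC at (non-zero mean)/ε; the exclusivity flag, not the capped
number, drives all counting.

Per-tissue summaries report detection ("any non-zero value after
imputation in either group") against two denominators — the union feature
count and the tissue's detected count — and partition significant features
into GF-only / MPF-only / shared. The partition is computed over
filter-passing features by default; `uniqueness_among="detected"` computes
it over all detected features instead.

**BH discreteness caveat.** Because the exact test's p values cannot go
below 2/252, a tissue in which exclusives are a small fraction of tested
features gives them q = (2/252)·m/k (k = count at the minimal p), which
exceeds 0.05 whenever that fraction is below ≈ 16%. Planted exclusives can
therefore be perfectly recovered by the presence caller yet fall short of
the q cut. This is a property of the analysis recipe itself, not an
implementation artifact; the `detected` accounting mode exists partly so
exclusive recovery can be audited independently of it.

### Multivariate stages

Rows are z-scored as (x − x̄_row)/SD_row before clustering; the SD uses the
sample convention (n − 1 denominator) by default, configurable to
population — the choice rescales every row by the same constant factor and
is recorded in the run config. Zero-spread rows are excluded and listed.
Clustering is Euclidean k-means (k = 10 default) with k-means++
initialization and 25 restarts under a fixed seed, applied to the
filter-passing features. PCA operates on the unscaled matrix: samples are
observations, each feature is mean-centered, no variance scaling;
intensities enter raw (a log option is deliberately absent from the default
path).

## The synthetic-data generator

The generator emulates the *statistical structure* the analysis assumes,
not raw spectra: no chromatographic peaks, isotopes, adducts, batch or
drift effects, and no QC samples.

Intensity model, on the natural-log scale, for feature f, tissue t, group
g, replicate r:

    ln x = b_f + τ_{f,t} + δ_{f,t,g} + ε,
    b_f ~ N(log_mean, log_sd²),  τ ~ N(0, tissue_effect_sd²),
    ε ~ N(0, replicate_sd²)

with δ = ±ln(2)·group_effect_log2fc applied to the GF block of planted
differential features. Per feature × tissue, a status is drawn: `absent`
(probability `frac_absent`, structural zeros in both groups), `GF_only` /
`MPF_only` (`frac_exclusive`, structural zeros in one group), `up_in_GF` /
`down_in_GF` (`frac_differential`), else `null`. A measured value is zeroed
by dropout with logistic probability
1/(1 + exp(steepness·(ln x − midpoint))) — monotonically non-increasing in
intensity — and whenever it falls below `detection_floor`. Every zero in
the output is thus attributable to structural absence or to dropout, which
is what gives the three imputation rules realistic targets.

Defaults and rationale (all on the configuration object, none inferred
from data):

| parameter | default | why |
| --- | --- | --- |
| feature counts per mode | 5961 / 3946 / 9256 / 5131 (HILIC±, RP±) | the design scale of the target study (24,294 total) |
| tissues, groups, replicates | 13 named tissues, GF/MPF, 5 | the study design |
| `log_mean`, `log_sd` | 12.0 (≈163k counts), 1.0 | typical detected-feature intensities sit well above the 10k imputation cut, consistent with a 100k high-abundance filter being meaningful |
| `tissue_effect_sd` | 1.2 | tissue is the dominant effect: larger than the group-effect dispersion (≈0.44 natural-log across features) |
| `group_effect_log2fc` | 2.0 | a planted 4-fold change, comfortably above the 1.3 filter but far from the volcano extremes |
| `replicate_sd` | 0.35 | ~35–40% CV, typical replicate noise for tissue LC–MS |
| `frac_differential`, `frac_exclusive`, `frac_absent` | 0.10, 0.05, 0.30 | hundreds of exclusives per tissue at design scale; detection rates ≈70%, within the observed 23–74% per-tissue range |
| `dropout_midpoint`, `dropout_steepness` | ln ≈ 2000 counts (7.6), 2.5 | dropout concentrated near the detection limit (4× the 500-count floor): misses are sporadic and mostly rule-3-repairable, rather than wiping whole groups |
| `detection_floor` | 500 | sub-threshold non-zero values survive it, so rule 2 has targets |
| `msms_prob` | 0.8 | the MS/MS criterion excludes a realistic minority |

Randomness is one `numpy` stream per feature, spawned from the global seed
via `SeedSequence(seed, spawn_key=(feature_index,))`, so output is
bit-identical regardless of iteration order or batching.

`replicate_sd`, `frac_absent`, `msms_prob` and the rt/mz ranges are
generator fields beyond the minimal knob set: replicate noise makes the
rank test non-degenerate, tissue-level absence realizes the `absent`
ground-truth status, and the MS/MS probability makes that filter criterion
exercisable.

**What passing tests show — and don't.** Recovery results on these tables
demonstrate that the pipeline's logic is correct under its own model
(log-normal intensities, additive effects, logistic dropout, independent
features). Real LC–MS data adds correlated features (adducts, isotopes,
in-source fragments), heavy-tailed and heteroscedastic noise, retention-time
structure in dropout, and batch effects; recovery rates measured here do
not transfer to such data, and nothing here validates upstream peak
picking or alignment.

## Numerical conventions

- Exact-test tie tolerance: rank sums are multiples of ½, so "at least as
  extreme" comparisons carry a 10⁻⁹ slack — far below the ½ quantum, so no
  labeling can be misclassified.
- Intensities are serialized at full `repr` precision and parsed with
  pandas' round-trip parser, so values straddling the 10,000 / 100,000
  thresholds cannot flip across I/O.
- Threshold comparisons: rule 2/3 routing treats a non-zero summary exactly
  equal to 10,000 as "above" (≥); all filter criteria are inclusive (≥/≤)
  as written; volcano criteria are strict (>, <) as written.
- Degenerate inputs: vectors shorter than 2, negative intensities,
  non-finite matrices, and constant rows (for z-scoring/PCA) raise typed
  errors or are excluded-and-reported rather than silently dropped.
- k-means with the same seed, data and restart count is bit-reproducible;
  empty clusters (possible in principle at small n) are reported by id.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` choose sizes that keep each
study statistically meaningful at desk scale: the design-scale run uses the
full 24,294 × 130 table; the null-calibration study uses 2,000 features ×
(5 vs 5) over 100–200 simulation replicates; planted-recovery studies use
3,000 features × 13 tissues; cluster recovery uses 150 rows across 20
seeds. These are the package's own choices of simulation size and are
recorded here so results can be reproduced exactly.

## Known limitations

- The exact enumeration is specialized to two groups; it scales as
  C(n₁+n₂, n₁) and is intended for small-replicate designs (≤ ~8 per
  group).
- The per-tissue FDR batch is a convention (configurable in spirit via
  direct use of `bh_fdr`); a global batch across tissues would give
  different q values.
- Group-exclusive features' fold changes are flags, not numbers; any
  display needing finite coordinates must opt into the ε-floor convention
  and state ε.
- The generator plants effects independently across tissues and features;
  it cannot emulate metabolite classes that co-vary across tissues (the
  pattern k-means is meant to reveal in real data), so cluster-recovery
  tests use separately planted archetypes instead.
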