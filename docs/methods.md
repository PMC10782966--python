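# Methods

This note documents the models, conventions and numerical choices behind
`lipidome`, in the order data flows through the pipeline.

## Shorthand nomenclature

Species are written `CLASS(term/term/...)[_isomer]`, one `carbons:double_bonds`
term per acyl-chain slot. Canonical slot counts are enforced: two for the
diacyl phospholipids (PG, PE, PC, PA), four for cardiolipin, three for the
glycerolipids (DG, TG — glycerol has three positions, so a diacylglycerol
carries one `0:0` placeholder), and two for the sphingolipids (sphingoid base,
marked by a `d` prefix, plus N-acyl chain). Three reporting conventions widen
the grammar:

- **Lyso forms**: a phospholipid with an empty slot, e.g. `PG(18:1/0:0)`.
  Only the glycerophospholipid classes are marked lyso; a `0:0` in DG/TG is a
  positional placeholder, not a lyso marker (a "lyso-DG" would be a
  monoacylglycerol, which the class token would then misname).
- **Sum compositions**: a single total term, e.g. `PG(35:1)`, when chain
  fragments were not resolved. Chain-level fields are unresolved; totals are
  valid and are what every downstream metric consumes.
- **Ambiguous dual annotations**: `PE(16:0/18:1)/PE(16:1/18:0)`. The first
  annotation is primary, the rest are retained as alternates. Dual annotations
  arise precisely because the assignments are isobaric, so alternates share
  totals and the choice of primary does not affect any metric.

`_A`/`_B` suffixes are chromatographic isomer labels: structurally identical
records that remain distinct feature IDs in matrices.

Headgroup net charge is a pure function of class: PG, CL and PA anionic; PC
and PE zwitterionic; DG, TG, Cer and HexCer neutral. Lyso variants inherit the
parent class's charge. Charge-composition *profiles* exclude PA by default
(see below).

## Normalization

Positive- and negative-mode tables are normalized separately, always.

- **Total-intensity normalization** divides each value by its (sample, mode)
  block total, yielding compositional relative abundances; used for class
  composition and charge profiles.
- **Log2-median scaling** log2-transforms and subtracts each sample's
  within-mode median (equivalently, divides by the median intensity before the
  log — the order of operations changes nothing for this operator; subtraction
  in log space is used). Input state for differential testing, clustering,
  PLS-DA and the biomarker procedure.

Missing peaks are NaN throughout: excluded from medians, contributing zero to
block totals, and tests use available replicates only (at least two per group,
otherwise the lipid is flagged untestable and excluded from counts). No
pseudocount is applied by default; a nonpositive intensity under the log2
scheme is an error unless `zero_policy="half_min"` is requested explicitly.

Median scaling assumes most features are unchanged between samples. When a
large fraction of lipids shifts in one direction (fraction *p*, shift Δ), the
sample median itself moves by ≈ *p*·Δ within the mode, and estimated fold
changes are compressed by that amount. This is inherent to the normalization,
not to the estimator: the generator-based checks show fold-change estimates
unbiased to within ±0.2 when ~2% of a mode is planted and compressed by
≈ 0.35 when ~15% of a mode shifts one-directionally. Interpret fold changes
from heavily asymmetric contrasts accordingly.

## Differential abundance

Per lipid, a two-sided equal-variance (Student's) t-test (df = nA+nB−2;
Welch available via `equal_var=False`) plus a log2 fold-change criterion.
Defaults are raw P < 0.05 and |log2 FC| > 1.5, with the stricter (0.01, 2.5)
pair used to narrow to the most discriminant species; Benjamini–Hochberg
adjustment is available behind `adjust="bh"` but off by default, matching the
threshold-pair filtering convention. Degenerate zero-variance inputs follow
the convention p = 1 for equal means, p = 0 (with a warning) otherwise.

The fold-change convention is **B_over_A**: positive means elevated in the
second-listed group. The convention is stored on every table so a reader can
always recover the direction.

"~" percentages in summaries round to the nearest integer, others to one
decimal; both helpers (`approx_percent`, `percent`) are exported rather than
baked into the tables.

The ANOVA screen ranks lipids by one-way ANOVA p-value across all groups
(ties: F descending, then ID), for selecting top-k heatmap panels. With two
groups it reduces exactly to the t-test (F = t²), which the tests exploit as
an identity check.

## Membrane indices

For lipids with total double-bond counts dᵢ, total acyl carbon counts Lᵢ and
abundance weights wᵢ:

    DBI = Σ dᵢwᵢ / Σ wᵢ        MCL = Σ Lᵢwᵢ / Σ wᵢ

Weights are **log2 raw intensities before median centering** (mean over the
comparison's samples): centered values can be negative, which breaks the
weighted-mean reading; callers insisting on centered values must shift them
positive and the primitive says so in its error message. Both indices are
computed over the differential lipids of a comparison by convention, with the
subset recorded on the result.

Per-lipid "chain length" is the **total** acyl carbon count over non-empty
chains, not the per-chain mean — the only definition that is also valid for
sum-composition species (the alternative, mean carbons per chain, is
computable from `chains` by any caller that wants it). DBI and MCL are proxies
for membrane unsaturation (fluidity) and thickness; no biophysical simulation
is implied.

Charge profiles aggregate total-normalized abundances per sample into
anionic = PG + CL, zwitterionic = PC + PE, neutral = DG + TG + Cer + HexCer.
The default basis excludes PA entirely — matching the conventional enumeration
used in net-charge composition figures — while `all_classes` counts PA as
anionic. PA is always recorded as anionic on the species itself.

## Multivariate procedures

**Clustering** is agglomerative on Euclidean sample distances with the
Ward.D2 criterion (Lance–Williams recurrence on squared distances, heights
reported unsquared), via SciPy's `linkage(method="ward")`, which is verified
in the tests against a brute-force agglomeration oracle. SciPy's
nearest-neighbor-chain algorithm resolves ties deterministically (by its chain
order rather than an explicit lowest-index rule); on generic data there are no
ties and the result is algorithm-independent. Lipids with any missing value
are dropped (complete-case) with a warning before clustering or any
multivariate fit.

**PLS-DA** fits a two-latent-variable PLS regression on a 0/1 class
indicator with autoscaled features (scaling refit inside every
cross-validation fold). Reported: leave-one-out nearest-class accuracy,
in-fit R² on the indicator, and Q² = 1 − PRESS/TSS under leave-one-out.

**Biomarker analysis** is multivariate exploratory ROC by Monte-Carlo
cross-validation. Each round: balanced subsample (majority class downsampled
to the minority size), stratified 2/3 train / 1/3 validation split, a random
forest fit on all lipids for feature ranking and validation AUC. Panels of
size k are refit per round on the top-k features of *that round's* training
importances, so validation samples never inform the panel they score — using
a globally averaged ranking instead leaks information across rounds and
inflates null AUCs far above 0.5. The reported overall ranking and selected
panel (default size 15) use mean importance across rounds. AUC is the
Mann–Whitney rank statistic with ties counted ½. Defaults: 100 rounds, 500
trees, √p features per split — conventional values, recorded in the report;
the round count the original interactive analyses used is not documented
anywhere, so these are this package's own defaults, not inferred ones. All
randomness flows from a single integer seed; results are bit-reproducible.

Permutation nulls for the biomarker statistic re-permute the labels for each
block of rounds. A single fixed permutation leaves the null statistic at the
mercy of that draw's chance whole-dataset feature–label correlations (spread
≈ ±0.1 in panel AUC across draws); re-permuting centers it at 0.5.

## Synthetic lipidome generator

The generator emulates the statistical shape the pipeline assumes, with
ground truth returned alongside:

- **Catalog**: 194 unique shorthand names over 13 subclasses (nine classes
  plus four lyso phospholipid forms), exercising every grammar feature, with
  a fixed reference corpus always included. Class → ionization mode follows
  the usual ESI polarity split (PG/PE/PA/CL negative; PC/DG/TG/Cer/HexCer
  positive).
- **Design**: planktonic growth at salinities {7, 13, 20} % NaCl × HRTs
  {19.2, 24, 48} h × 3 replicates (n = 27) plus a biofilm arm at 3 salinities
  × 3 replicates (n = 9); a two-group convenience design for calibration and
  power studies.
- **Noise model**: per-lipid log2 baselines uniform on [10, 25] (a realistic
  LC-MS dynamic range) with Gaussian replicate noise, σ = 0.5 log2 units by
  default; intensities are 2^(baseline + effects + noise), so log2 values are
  normal per group, consistent with t-testing. Planted effects are applied on
  the log2 scale, making ground-truth fold changes exact.
- **Missingness**: completely-at-random at a configurable rate, but never
  wiping an entire replicate group of any lipid.

What the generator does *not* emulate: intensity-dependent missingness,
heteroscedastic or correlated noise across lipids, retention-time drift,
adducts, or class-correlated abundances. Passing tests therefore demonstrate
correctness of the statistical machinery under its stated assumptions, not
robustness to every pathology of instrument data.

## Problem sizes used in the checks

The automated checks run the calibration study at 2,000 null lipids (3 vs 3),
the recovery study at 200 simulated datasets (20 of 194 lipids planted at
Δlog2 = 3, σ = 0.5), the biomarker study at 18 vs 18 samples with 15 planted
discriminators (30 MCCV rounds; the permutation null uses 10 permutations × 5
rounds), and oracle comparisons at 6 samples (clustering) and 10 samples
(AUC). These sizes give stable statistics while keeping the full check suite
runnable in a few minutes on one core.

## Known limitations

- The parser covers exactly the shorthand dialect described above: no
  ether/plasmalogen linkages, oxidized lipids, adducts or isotopes, and
  sphingoid hydroxylation beyond the `d` flag is not modeled.
- A lipid identified in both ionization modes is an error at merge time;
  reconciling duplicate identifications is upstream work.
- Fold-change compression under heavily asymmetric contrasts (see
  Normalization) is a property of median scaling the pipeline inherits.
- `ClusterResult.cut` and leaf order depend on SciPy's deterministic
  tie-handling; dendrograms with exactly tied merges may differ from other
  implementations in child order, not in heights.
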