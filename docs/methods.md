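# Methods

## Scope and data model

The package operates downstream of peak picking: its inputs are per-mode
peak intensity tables (biological samples plus pooled QC samples at
dilutions 0.25/0.50/1.0), a theoretical lipid library keyed by
(class, total carbons, total double bonds, ionisation mode) with a
theoretical m/z in [150, 1200] Da, a study design (groups and
genotype-matched replicate comparisons), curated species lists where sum
compositions cannot identify fatty acids, and metabolite response tables
with calibration standards. Raw spectra, isotope envelopes, adducts and
chromatography are out of scope.

Missing measurements are encoded as NaN, distinct from zero; observed zeros
are recoded as missing at the presence filter and before normalization,
since a zero reading on this platform means "not measured" rather than
"absent".

## QC retention rules

Boundary semantics are taken literally from the protocol the package
implements: a variable is discarded when it deviates by **more than** 9 ppm
(exactly 9 passes; the comparison carries a 1e-9 relative guard so the
boundary decision is stable under floating-point rounding of the ppm ratio),
when its dilution correlation is **not above** 0.75, when its median
signal-to-noise is **below** 3 (exactly 3 passes), or when it is present in
**fewer than** 50% of biological samples (exactly half passes).

- The linearity correlation is Pearson's r between raw intensity and
  dilution factor (the protocol names only "correlation"; Pearson on raw
  intensities is assumed and the threshold is configurable). A zero-variance
  response leaves r undefined and fails: a flat response is not
  proportional to concentration.
- S/N uses the variable's median biological intensity over a per-variable
  noise estimate supplied with the table; noise estimation from raw scans is
  upstream of this package.
- Ambiguous peak-to-library matches are resolved by minimal ppm deviation,
  ties by lower theoretical m/z; when two peaks claim one library entry the
  closer wins and the loser is logged as unassigned.
- Filters are evaluated in the fixed order ppm → linearity → snr → presence.
  The retained set is the intersection of all four passes and is therefore
  order-invariant; only the recorded `rejection_reason` (the first failure)
  depends on the order. Without QC samples the linearity stage is skipped
  with a prominent warning in the report.

## Normalization and aggregation

Per-mille values are intensity divided by the per-sample sum of non-missing
intensities, times 1000; missing values are excluded from the denominator
and stay missing. Aggregation treats missing as zero so group sums are
always defined; both conventions are deliberate and recorded here because
they interact (a group sum over a partially missing sample is a lower
bound, while the sample total used for scaling reflects only measured
signal).

Positive- and negative-mode tables are normalized and analysed
independently throughout; grouped plots and the LC-PUFA split **sum**
member abundances (rather than averaging), which makes a partition of a
class conserve the class total exactly.

LC-PUFA content is compositional for glycerides — TG with ≥54 carbons and
≥5 double bonds, DG with ≥38 and ≥5 — and list-based for PC: a sum
composition like PC(38:6) cannot reveal which fatty acids it contains, so
curated (fragmentation-derived) species sets are an *input*. The pipeline's
synthetic runs use a stand-in set (PC with ≥5 double bonds), labelled as
synthetic in its provenance note.

## Statistical kernel

- **Student t**: pooled-variance, two-tailed, complete-case per variable
  (Welch available behind a flag). Two constant, equal groups define the
  exact null (t = 0, p = 1). Direction is the sign of mean(b) − mean(a),
  with b the pregnant (or DLK1-deficient) side.
- **√n-Bonferroni**: α = 0.05/√n. n is the *combined* retained-variable
  count across both ionisation modes per tissue even though tests run per
  mode — the only reading that reproduces all three printed thresholds
  (456 → 0.00234, 312 → 0.00283, 38 → 0.00811). This deliberate
  under-correction relative to 0.05/n is paired with the multivariate
  selection and the replication rule below.
- **Šidák**: 1 − (1 − p)^m with m the number of post-hoc contrasts in the
  family, derived from the grouping rather than hard-coded.
- **Two-way ANOVA**: fixed effects with interaction, Type III sums of
  squares under sum-to-zero coding (robust to imbalance; statsmodels OLS
  underneath). Empty cells drop the interaction with a warning. Post-hoc:
  condition contrasts within each category level against the full-model
  residual mean square, Šidák-adjusted.
- **PCA outlier exclusion**: variables autoscaled, samples projected onto
  two principal components, and excluded when their Hotelling T² exceeds
  2(n−1)/(n−2)·F₀.₉₅(2, n−2). Autoscaling makes the decision invariant to
  per-variable units. Fewer than 4 samples: no exclusion, warning.
- **Sparse PLS-DA**: NIPALS PLS1 on autoscaled X against a centred class
  indicator. Per component the weight vector is hard-thresholded to the
  keepX largest absolute entries and renormalized; X is deflated by the
  component loading. With keepX = p this reproduces dense PLS-DA scores
  (verified against scikit-learn to 1e-8 cosine). "Selected" means a
  nonzero loading on any of the first 2 components with keepX = 10 each —
  MetaboAnalyst-style defaults, all configurable, since no sharper
  definition of "passing" the multivariate test exists. Components are
  oriented so the second-listed group's mean score is positive; constant
  columns are dropped with a warning.
- **Pearson matrices**: pairwise-complete correlation with exact-t p-values;
  pairs with <3 complete observations are undetermined. The significance
  threshold (0.0045 in the motivating gene-panel analysis) is an input
  parameter, never derived.

## CBM rule

A variable is a candidate biomarker when it passes *both* the thresholded
t-test and the sPLS-DA selection in at least two genotype-matched replicate
comparisons of one replicate set and one mode, with a consistent direction
across the passing comparisons. Direction consistency is this package's
explicit choice (a single direction is reported per biomarker and
conflicting directions are not meaningfully replicated); inconsistent
variables are emitted with a flag and `is_cbm = False`, and the requirement
is switchable. For replicate sets with exactly two comparisons
(fetal/maternal effect) the rule degenerates to "both". PCA outlier
exclusion runs per comparison before testing. For the multivariate steps
(PCA, sPLS-DA) missing values are column-mean imputed; the t-tests remain
complete-case.

## Metabolite stage

Calibration is weighted least squares with weights 1/X over 10 standards
per compound spanning 0.95–500 ng/mL. LOD/LOQ are the lowest standards with
S/N strictly above 3 and 10 (first qualifying level even if the ladder is
non-monotone); compounds never reaching S/N 3 are flagged not detected.
Back-calculated concentrations below the LOQ are censored — excluded, not
imputed — and censored values count as missing in the CBM tests.
Metabolites quantified in under half the samples are dropped with a
warning; the remaining count sets the 0.05/√n threshold. Per-standard S/N
values are inputs (chromatogram-level noise estimation is out of scope).
The packaged panel lists 45 compounds with pathway (COX, LOX, CYP450,
beta-oxidation, non-enzymatic) and precursor (ARA, EPA, DHA, LA, ALA,
other) annotations from standard eicosanoid biochemistry; 7 compounds are
flagged never-detected, leaving 38 quantifiable.

## Synthetic cohorts: what they emulate and what they do not

Biological intensities are log-normal: ln I = ln(baseline) + ln 2 · log2FC
(per the sample's group and the planted effect kinds) + N(0, σ). Defaults:
σ = 0.2 (natural-log scale), 7 mice per group (the emulated study used
6–8), baselines log-uniform over 3 decades so normalization is exercised
across magnitudes, 2% sporadic missingness, pooled QC samples at each
dilution with 5% multiplicative noise, m/z jitter uniform within ±5 ppm so
clean variables always pass the 9 ppm gate. Planted pregnancy effects
mirror the emulated study's qualitative findings: TG up, high-unsaturation
PC/PE up, low-unsaturation down, plus strong species-level spikes that act
as ground-truth biomarkers; a maternal-genotype effect on PE(38:4) exercises
the second replicate set. The true effect-size and variance magnitudes of
the real data are unknown; defaults are chosen to make the closed-loop
tests well-powered, not to match mouse biology, so passing tests validate
the *procedure*, not any biological claim.

Decoys violate exactly one retention criterion each, with margin: mass
displacement 12–30 ppm (library spacing ≥0.05 Da guarantees no
cross-annotation), true S/N 1.2–2.5, missingness >60%. The nonlinear-QC
decoy is realized as an *inverted* dilution response (intensity decreasing
in dilution factor): a flat response fails a correlation threshold only
stochastically under noise, and a saturating one on three dilution levels
is still strongly rank-correlated with concentration, so inversion is the
realization that violates the r > 0.75 criterion deterministically.

The fixture preset (60 variables, 6/group) narrows the baseline spread to
1.5 decades and keeps class-wide effects modest (±0.2–0.3) around ±1.5
species spikes: per-mille data are compositional, and in a 24-variable mode
a dominant baseline or a large total-signal shift materially erodes the
relative contrast of a planted species. The paper-sized presets keep the
3-decade default.

Known unmodelled features of real DI-MS data: ionisation-efficiency
differences between classes, isotope overlap, adduct splitting,
batch/run-order drift, and correlated biological covariance between lipid
species (variables are conditionally independent given their group here).
Compositional coupling through the per-mille denominator *is* reproduced —
and the synthetic runs show the expected artifact that strong class-wide
shifts can drag passive variables past univariate thresholds, one reason
the CBM rule demands multivariate agreement and replication.

## Problem sizes and runtime

The default test suite runs the fixture cohort (60 variables, 8 groups × 6)
for the closed-loop checks and paper-sized cohorts (456/312 variables +40
decoys, 7/group) for the QC-ledger and threshold checks. The null-calibration
and sensitivity properties use 200 simulated cohorts each at 456 variables,
3 comparisons and n = 7/group, with vectorised complete-case t-tests; each
block completes in well under a minute on one CPU.
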