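# Methods

## Flux stress-test model

A stress-test trace is modeled as a piecewise-constant rate process: the
well sits at a plateau rate within each injection segment, and each
measurement cycle observes that plateau plus additive Gaussian noise (and an
optional linear drift term, default 0, kept so the plateau estimator can be
stress-tested). Segments are half-open on the right: the cycle index at
which a compound is injected belongs to the preceding segment. Time is in
minutes; ECAR in mpH/min, OCR in pmol O₂/min.

**Plateau estimation.** The level of a segment is the mean of its last
`min(k, n)` cycles, default k = 3 (the conventional three measurement
cycles per segment on an XF24 run). For non-first segments with more than k
cycles, the first post-injection cycle is dropped before taking the last k,
to exclude the mixing/equilibration transient. With the default 3 cycles
per segment the estimator reduces to the segment mean.

**Metric definitions.** Glycolysis stress test (segments baseline → +glucose
→ +oligomycin → +2DG): non-glycolytic acidification = baseline level; basal
glycolysis = glucose − baseline; glycolytic capacity = oligomycin −
baseline; reserve = capacity − basal; utilization = basal/capacity.
Mitochondrial stress test (baseline → +oligomycin → +FCCP →
+rotenone/antimycin A): non-mitochondrial OCR = rot/AA level; basal
respiration = baseline − non-mito; ATP-linked = baseline − oligomycin;
proton leak = oligomycin − non-mito; maximal = FCCP − non-mito; spare =
maximal − basal; utilization = basal/maximal. The identities reserve =
capacity − basal, spare = maximal − basal and ATP-linked + leak = basal hold
exactly by construction on every input.

Negative derived values (possible under noise or assay failure) are
reported as computed with a warning flag, never clamped: clamping would
hide failed runs, and no clamping rule is part of the assay's definition.
Rates are normalized per 10⁴ cells (post-run counts) by multiplying every
rate field by `unit_cells / cell_count`; utilization fractions are ratios
of rates and are invariant under this normalization and under any uniform
rescaling, which is tested. Because all metrics are linear in the levels,
normalizing before or after metric computation is equivalent.

**OCR/ECAR ratio.** The oxidative-vs-glycolytic preference index is basal
respiration over basal glycolysis, computed from paired ECAR and OCR plates
of the same condition after per-cell normalization; the condition-level
ratio uses the across-well mean of each basal rate, and the contrast is the
suspension/adhesion ratio fold. Using raw baseline levels instead of
basal-above-background rates is a defensible alternative; the
basal-over-basal definition was chosen because both quantities are already
background-corrected and cell-normalized.

**Condition comparison.** Per metric: across-well arithmetic mean, sample
SD, fold versus the reference condition, and a two-sided Welch
(unequal-variance) t-test. Welch is used for all two-group comparisons in
the package; with fewer than two wells on either side the test is skipped
with a warning and the fold is still reported.

## Expression screen

Intensities are assumed positive and already normalized (the pipeline
accepts normalized matrices; background correction is upstream of this
package). Multiple probes per gene are collapsed by arithmetic mean on the
intensity scale. Per (gene, line), replicates are averaged per condition
first, then r = (Ī_susp − Ī_adh)/Ī_adh; averaging per-replicate ratios
instead would estimate a different (bias-prone) quantity and is not
offered. r is invariant under per-line rescaling of intensities.

Keyword selection over gene-set collections searches name and description
by default (database keyword queries match annotation text, and some
glucose-metabolism sets do not carry the keyword in their name); name-only
search is available. The candidate universe is the first-appearance-ordered
union of the selected sets' members.

The screen calls a gene down (up) when r < −τ (r > +τ) in **every** line,
with strict inequalities and alphabetical output. τ defaults to 0 in
`consistent_direction_screen` (pure sign agreement). The pipeline default
is τ = 0.10, chosen from the fixture's geometry before any recovery run:
with replicate noise at 5% of intensity and 3 replicates per condition, the
sampling SD of r is ≈ 0.05·√(2/3) ≈ 0.04, so τ = 0.10 sits > 2.4 SD above
the null and > 3.6 SD below the weakest planted effect (0.25). At τ = 0 a
null gene has probability 2·(1/2)⁴ = 12.5% of chance sign-consistency
across four lines, so a ~1,000-gene universe would produce ~120 false calls
— pure sign agreement is only a meaningful filter when measurement noise is
negligible relative to effect sizes.

The transporter panel (MCT1/SLC16A1, MCT2/SLC16A7, MCT4/SLC16A3,
GLUT1/SLC2A1) reports signed percentages to one decimal and marks cells
with |r| ≥ 0.35, the threshold that separates "clearly changed" from
"partly changed" entries in this panel (e.g. −38.4% marked, −28.6% not);
it is configurable.

## Assay quantifications

* **qPCR:** ΔCt = Ct(target) − Ct(GAPDH) per group using replicate-mean
  Cts; ΔΔCt = ΔCt(test) − ΔCt(control); fold = 2^−ΔΔCt. Replicate SD is
  propagated on the ΔΔCt (log₂) scale. The calibrator is the adhesion
  group.
* **Proliferation:** ratio of mean cell count at a glucose concentration to
  the mean count at the normal-culture concentration, per condition.
* **ROS:** relative percent = 100·(F − F_neg)/(F_pos − F_neg) against the
  antimycin-A (positive) and N-acetylcysteine (negative) controls — a
  min–max anchoring that is invariant under affine transforms of the
  fluorescence channel. Folds between samples are ratios of percents; both
  the percents and the folds are reported since either convention appears
  in practice.
* **Lactate:** condition means ± SD per pH with Welch comparisons between
  conditions at fixed pH.
* **Drug sensitivity:** viabilities are normalized to the vehicle (dose-0)
  mean per (condition, compound), clipped to [0, 1]; the score is 1 minus
  the trapezoidal mean of normalized viability over the log₁₀-dose grid.
  This normalized-AUC score is ordinal (higher = more sensitive), defined
  even for curves that never cross 50% viability, invariant under signal
  rescaling, and monotone in pointwise viability — IC50 fitting is
  deliberately avoided because the comparisons of interest are ordinal and
  several real curves are too shallow for a stable midpoint fit.

## Synthetic-data generators and the mirror fixture

Every generator is a pure function of its spec including the seed; each
table draws from a named child RNG stream derived from (seed, table name),
so generators are mutually independent and adding one never changes
another's output. Ground truth (planted plateaus, per-(gene,line) effects,
folds, dose–response parameters) is serialized as JSON next to the data.

Noise models: additive Gaussian on flux rates (SD = 5% of each trace's
plateau range by default) and on Ct values (SD 0.1); log-normal baselines
across genes/lines with multiplicative Gaussian replicate noise (fractional
SD 5%) for expression; additive Gaussian on fluorescence, lactate and
viability. These match mean ± SD reporting conventions and bead-array
intensity behavior; they do not attempt to model heavier-tailed outliers,
probe cross-hybridization, batch effects, or plate-position effects, so
recovery results bound what is achievable under well-behaved noise, not
under real-array pathology.

The mirror fixture fixes the study conditions in one place: 4 lines ×
2 conditions × 3 replicates; 1,005-gene universe covered by 29
"glucose"-matching sets (a few matching only in their description) plus 11
decoy sets; 10 planted-down and 7 planted-up genes with per-line effect
magnitudes uniform in [0.25, 0.65]; the transporter-panel genes and NOX4
(planted at +74% in all lines) live in the expression matrix but outside
the gene-set union, so the screen universe stays at exactly 1,005. Flux
plateaus are planted to satisfy the study's contrasts simultaneously:
suspended OCR (30, 10, 62, 2) ⇒ utilization 28/60 = 0.467; adherent OCR
(17, 10, 17, 2) ⇒ zero spare capacity and a 60/15 = 4.0 maximal fold; ECAR
plateaus put both conditions at 80% capacity utilization with basal rates
(28.2857 vs 16 after background) that make the OCR/ECAR ratio fold exactly
3.3. Wells carry 5×10⁴ cells; rates are reported per 10⁴ cells.

A note on the 80% figure: "80% of capacity" can be read as the utilization
fraction or as the reserve fraction, and the two cannot both be 80%. The
module reports both quantities (utilization and reserve) on every run; the
fixture plants utilization = 0.80.

## Problem sizes and estimator stability

Recovery analyses use 200 simulated traces per utilization estimate
(median absolute error ≈ 0.024 at the 5%-of-range noise), 50 paired plates
for the ratio/maximal folds (per-pair SD of the ratio fold ≈ 0.2, so the
50-pair mean has SE ≈ 0.03), 100 regenerated studies for screen recovery,
and 25 regenerated studies/tables for panel percentages and assay folds.
These sizes were chosen so each summary's Monte-Carlo error is small
against the quantity it estimates.

## Known limitations

* The GEO series-matrix importer handles the standard header + table-block
  layout and requires a user-supplied sample-title → (line, condition)
  mapping; it does not fetch from the network or parse supplementary files.
* The screen is direction-only by design: it inherits the original
  analysis's lack of a significance model, and τ is the only guard against
  noise-driven calls.
* Dose–response sensitivity is ordinal; absolute scores depend on the
  tested dose grid and are only comparable across conditions measured on
  the same grid.
* The synthetic generators plant condition effects that are homogeneous in
  sign and magnitude range; real detachment responses are heterogeneous
  across lines beyond what the fixture emulates.
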