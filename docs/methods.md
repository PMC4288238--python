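# Methods

## The deconvolution model

Tissue-level expression is treated as a sum of cell-population
contributions. For gene *g* and sample *s*,

    y_gs = β_0 + Σ_k β_gk · r_ks + ε_gs,     ε_gs ~ iid N(0, σ_g²),

with one reference signal `r_k` per population. The model is linear in
population abundance, so it must be fitted on **linear-scale** intensities;
input matrices whose maximum value is below 30 are assumed log2-encoded and
are exponentiated on load (linear microarray intensities are orders of
magnitude larger; the flag is recorded on the dataset). The standard bulk
analysis, by contrast, works on log2(x+1) as usual.

## Reference signals

Each marker probeset is scaled so its across-sample mean is exactly 100,
giving markers equal weight regardless of absolute intensity. Scaled
probesets reporting the same gene are averaged into a gene measure;
gene measures are averaged into the cell-type signal. The order matters:
with three NEFL probesets and one ENO2 probeset, averaging probesets first
prevents NEFL from dominating the neuron signal threefold. Each resulting
column has mean exactly 100 and is invariant to rescaling any input
probeset by a positive constant.

Marker quality control computes mean pairwise Pearson correlations across
samples: within a cell type the mean must exceed 0.5 for the type to be
usable; between types the mean is compared against an advisory 0.05 bound
(signed correlations by default, with an absolute-value option — the
thresholds refer to signed values as conventionally quoted, and the signed
default is recorded here deliberately). Zero-variance probesets have
undefined correlations and are excluded from the means with a warning.
Within-type QC with fewer than two usable probesets is a vacuous pass,
also warned about.

## Model selection and quality filters

With four candidate regressors there are only 15 non-empty subsets, so the
selector enumerates all of them exhaustively rather than using stepwise
search — deterministic, and never worse under the same criterion. AIC is
computed as `n·log(RSS/n) + 2(k+1)` (Gaussian likelihood, intercept counted,
additive constants dropped); this ranks models identically to the common
statistics-package conventions at fixed *n*. Ties resolve to fewer
regressors, then to the fixed cell-type order (neuron, astrocyte,
oligodendrocyte, microglia). When a fit is numerically exact (RSS below
1e−12 of the total sum of squares), RSS is clamped to a common floor so the
comparison between an exact fit and its supersets is decided by the
parameter penalty, not by float noise of order 1e−25.

Selected models pass quality control iff:

| criterion | threshold (default) |
|---|---|
| overall F-test | p < 0.05 |
| adjusted R² | > 0.6 |
| Shapiro–Wilk on residuals | p > 0.01 |
| intercept magnitude | ≤ mean expression / 2 |
| cell-type coefficients | all ≥ 0 |

All thresholds are configurable (`QualityThresholds`). Residuals that are
zero to machine precision are treated as passing normality (the test would
otherwise reject its own rounding noise). Zero-variance probesets are
skipped with a recorded reason; rank-deficient candidate designs are simply
not candidates. Marker probesets are removed from all final tables.
Passing models define the package's cell-type **expression assignments**
(gene × cell type), the quantity validated against external cell-type-
resolved data.

## Differential expression

For each selected model and each member cell type, an interaction column —
the reference signal on disease samples, zero on controls — is added and
the augmented model refitted. The interaction coefficient's two-sided
t-test is the DE p-value; control slope + interaction = disease slope, and
`log2FC = log2(disease/control)` (defined only when both slopes are
positive; other cases are flagged). The interaction columns are added one
at a time.

Two deliberate design choices here:

- **Which models are tested.** Quality gating of the *final DE table* uses
  the re-assessed augmented model, not the interaction-free base model. A
  gene whose per-cell expression genuinely changes cannot fit the base
  model well (its residuals are group-split, failing normality and R²
  gates), so gating DE on the base fit would exclude exactly the strongest
  effects; with a composition shift the bias is worse, because
  disease-correlated signals absorb the change as negative coefficients.
  All AIC-selected models are therefore tested by default
  (`only_passing_models=True` restores the stricter behavior).
- **Sign rules in re-assessment.** The interrogated cell type's control
  coefficient and implied disease slope must be non-negative; the
  interaction coefficient may be negative (down-regulation), and incidental
  co-regressors are not re-gated — their small sign flips after the
  interaction is added are fit noise.

The headline filter is unadjusted p < 0.05 (configurable), as is
conventional for this analysis; Benjamini–Hochberg FDR across all testable
pairs is reported alongside but not applied by default. Degenerate designs
(all-control, all-disease, collinear interaction) are flagged untestable.

## Single-cell-type mode

Where within-type marker correlations collapse (observed in basal-ganglia
tissue for astrocyte and oligodendrocyte signatures), four-population
modeling risks misassignment. The fallback screens every probeset against
all four reference signals — exclusivity must hold against every
population, including untrusted ones — and assigns a probeset to a type iff
its Pearson r with that signal exceeds 0.8 while signed r with the other
three stays below 0.2. Assigned probesets of the trusted types are fitted
with intercept + one reference + its interaction, under the same quality
filters and DE test. By construction this mode cannot see genes expressed
in several cell types, nor genes of the untrusted types.

`concordance_with_standard` reports |std ∩ alt| / |std| on significant
probeset ids, pooled and per cell type.

## Standard bulk comparison

Per-probeset two-group tests on log2(x+1): ordinary equal-variance t, or
(default) the empirical-Bayes moderated t — per-gene variances are shrunk
toward a scaled inverse-chi-square prior fitted by matching the moments of
log s² (prior df via a Newton inversion of the trigamma function), and the
t statistic gains the prior degrees of freedom. The implementation agrees
with the Bioconductor reference implementation to ~1e−3 on t statistics in
the test suite. The paired report classifies each probeset as concordant /
deconvolution-only / bulk-only / sign-discordant and provides per-probeset
regression-plot and box-plot data (and figures via the CLI).

## Validation tallies

Expression assignments are corroborated against cell-type-resolved
expression tables (e.g. from sorted cultures or translating-ribosome
profiling, mapped across species with a static ortholog table; duplicate
foreign ids collapse by maximum). A gene supports its assignment when the
table's value in that cell type exceeds 100 arbitrary normalized units
(configurable; ties fail). Fractions are reported as "81% (210/259)"
strings with explicit numerators and denominators. DE calls are checked
against independent per-gene DE tables (e.g. from laser-microdissected
neurons): a gene is validated by a source iff that source has p < 0.05 and
a same-sign fold change; summaries count genes validated by ≥ 1 and ≥ 2
sources.

## The synthetic-data generator

The generator emulates a case/control brain cohort: per-sample latent
abundances for the four populations are Gamma-distributed (positive,
right-skewed) with configurable means, CV (default 0.3) and a disease-group
multiplicative shift — stable composition by default; the
neurodegeneration pattern (neuron ×0.6, astrocyte ×1.5, oligodendrocyte
×1.2, microglia ×1.4) ships as a named preset. Defaults: 16 control and 18
disease samples, 2000 genes, 4 marker genes per type expressed in exactly
one population, per-cell expression levels uniform on [50, 500], support
sets of 1–4 types with probabilities (0.55, 0.25, 0.12, 0.08). Disease
effects multiply the cell-type-specific expression of chosen genes in
disease samples only — precisely the slope change the interaction term
models — and are forbidden on markers so the reference signals stay
faithful (marker corruption is a separate stress fixture in the tests).

Noise is additive Gaussian, homoskedastic per gene: sd equals
`noise_sd_fraction` times the gene's mean expected signal, constant across
samples, with final values truncated at zero. This matches the iid-residual
model the regressions assume (and gate on via the Shapiro test); it does
not emulate intensity-dependent variance, probe effects, normalization
artifacts or batch structure. The default fraction is 0.05, at which the
reference signals track the latent abundances with r > 0.99. Consequently,
passing tests demonstrate correctness of the machinery and calibration
under the model's own assumptions — not robustness to the full error
structure of real arrays.

## Measured statistical properties

Problem sizes in the test suite and acceptance script are chosen desk-scale
(500–2000 genes, 34 samples, 10 seeds for calibration runs). On these:

- Noiseless mixtures: the selector recovers the true regressor support for
  100% of genes and coefficients to ~1e−14 relative error; selection always
  agrees with an independent brute-force enumerator on noisy runs.
- Under the null (no effects, 20% noise), the interaction test's type-I
  error pooled over 10 seeds is within the 99% binomial band around 0.05
  when measured over base-passing models. Per-seed rates vary more than
  binomial (each run shares one abundance draw).
- Under a composition-only change the bulk test's positive rate among
  neuron-expressed genes is >0.5 while the interaction test shows no excess
  over nominal — in fact it is mildly *conservative* (~0.02–0.03): model
  selection on a design whose regressors correlate with the group label
  distorts the subsequent test toward under-rejection. A fixed,
  correctly-specified model is exactly calibrated. This
  selection-then-test conservatism is a known property of the procedure.
- Planted neuron effects (fold 0.5, 2% noise) are detected with the correct
  sign and log2FC within ±0.15 of −1 for ≥9/10 genes; fold-change errors
  beyond sampling noise arise when AIC picks a wrong support under the
  structural misfit a strong effect induces in the base model.
- The single-cell-type mode's concordance with the full mode on synthetic
  cortex-like runs is well below the ~70% reported on real cortex data:
  the synthetic significant lists contain nominal-rate calls the restricted
  mode cannot reproduce, and the 0.8/0.2 screen is sensitive to the chance
  cross-correlations of independent abundance draws (sd ≈ 0.17 at n = 34).
  The formula itself is exact and unit-tested.

## Known limitations

- Reference signals are abundance *proxies*; marker noise propagates into
  the design matrix (errors-in-regressors), mildly attenuating coefficients.
- A strong expression change degrades the base model's fit and can distort
  AIC support selection for that gene (see above); re-selection after
  adding the interaction is not attempted.
- The single-cell-type screen, computed on pooled samples, penalizes
  genuinely exclusive genes with large disease effects unless abundance
  spread is wide; this mirrors its intended use in tissues with severe,
  variable degeneration.
- No probe-level modeling, normalization, or batch correction; inputs are
  assumed preprocessed. Bit-exact parity with any particular bulk-DE
  package is out of scope (the moderated t agrees closely, not exactly).
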