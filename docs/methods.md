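# Methods

This note documents the models implemented in `cinp`, their assumptions, the
defaults that matter, and the choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Persistent random walk model

A migrating cell is modeled as a 2D persistent random walk: its velocity
decorrelates exponentially with persistence time *P* (min) while its
root-mean-squared speed is *S* (μm min⁻¹). The time-averaged MSD of such a
walk, observed with independent Gaussian positional error σ per coordinate
per frame, is

    MSD(τ) = 2S²P(τ − P(1 − e^(−τ/P))) + 4σ².

Short lags are ballistic (≈ S²τ²), long lags diffusive (≈ 2S²Pτ), and the
static tracking error contributes a constant 4σ² floor (σ² at each of two
endpoints in each of two coordinates).

### Simulator

The generator integrates a stationary Ornstein–Uhlenbeck velocity process
exactly: per coordinate the velocity has variance S²/2 and correlation time
*P*, and for each frame the position increment and end-of-frame velocity are
drawn from their exact joint Gaussian law (conditional on the current
velocity). Because no Euler discretization is involved, the ensemble MSD
equals the closed form above at *every* lag, not only as dt → 0; the
acceptance suite verifies agreement within 5% from 200 tracks. Positional
noise is i.i.d. Gaussian per frame per coordinate, matching the 4σ² term.
Defaults mirror the tracking protocol the pipeline targets: dt = 2 min,
duration = 48 h.

Assumptions the simulator does *not* capture: anisotropic persistence,
speed–persistence coupling, cell division (two-regime tracks are composed
explicitly in tests), and confinement by matrix structure.

### MSD estimation

`compute_msd` uses all overlapping start times per lag (the time-averaged
estimator) and records the pair count n(τ) = N − k per lag. The default
maximum lag is 1/3 of the track duration: beyond that, estimates rest on few,
strongly correlated pairs. Non-uniform time stamps are rejected rather than
resampled, since the targeted tracking protocol is strictly periodic.

### Fitting

`fit_prw` minimizes pair-count-weighted *fractional* residuals
√(n(τ)) · (model − MSD)/MSD with bounded positive parameters
(S ∈ (0, 100·S₀], P ∈ [dt/10, 30·τ_max], σ ∈ [0, 100] μm). Fractional
residuals matter: long-lag MSD values are orders of magnitude larger than
short-lag ones and their ensemble fluctuations are strongly correlated, so an
absolute-residual fit lets a few-percent long-lag wiggle corrupt *P* by tens
of percent. Two further numerical choices:

- the constant term is fitted internally as the noise floor nf = 4σ²
  (linear in the model); the derivative of 4σ² vanishes at σ = 0 and stalls
  gradient steps when the true noise is zero;
- the optimizer (lmfit least-squares, tolerances 1e-15) is multi-started
  over a small (P₀, σ₀) grid with S₀ solved from the last lag, because the
  SSE surface has local minima trading the noise floor against *P*.

S₀ defaults to √(MSD(τ₁))/τ₁, the short-lag ballistic estimate of speed.
A purely ballistic curve pegs *P* at its upper bound (the model tends to
S²τ² as P → ∞); this is reported via the `at_bound` field rather than an
error. Fits are per-cell by default; `ensemble_msd` pools curves weighted by
pair counts for per-condition fits, which is what the division-switch tests
use (single-track fits of short-persistence cells are noisy by nature).

## Planted expression datasets and module discovery

The generator emulates a 3-cell-line (two cancer, one normal fibroblast) ×
2-condition × 3-replicate design with 2000 genes. Gene baselines are
log-uniform on 10–500 TPM; each cell line applies an additional per-gene
log-normal identity factor (CV 0.5 by default) shared by both conditions, so
cell type dominates raw variance — as in real transcriptomes — while
cancelling exactly in within-line fold changes. Planted modules (70 genes
common to the cancer lines, 35 common to all, fold change 2) multiply the
high-condition mean only. Replicate noise is multiplicative log-normal with
unit mean and CV = 0.1 by default; the paper-style design gives no replicate
noise model, and a log-normal CV is the standard minimal choice for positive
expression data. At CV = 0 the realized ratios equal the planted fold
changes exactly, which the recovery tests exploit.

Module discovery: genes are *detected* at mean TPM > 5 (strict, across all
samples); per line, *upregulated* means (mean_high + c)/(mean_low + c) ≥
threshold on replicate means, default threshold 1.5 and pseudocount
c = 1 TPM. The pseudocount avoids infinite ratios at zero counts and is
negligible at TPM ≫ 1, but it does shrink ratios of low-expressed genes —
the constructed-invariance test therefore passes c = 0 explicitly.
Upregulation is one-directional (high > low); detection is applied before
fold-change so module genes are quantifiable in all lines. The Venn
partition emits every membership block; `common_to_cancer` subtracts the
union of normal-line sets from the intersection of cancer-line sets.

Enrichment uses the one-sided hypergeometric upper tail with BH step-up
adjustment across tested terms and a default background of *detected* genes
(standard overrepresentation practice when the assay, not the annotation,
defines what could have been observed). Annotation maps are flat term → gene
sets (GMT); no GO-hierarchy propagation is performed.

The z-score transform standardizes each gene within each cell line;
zero-variance genes map to 0. PCA separation is summarized as silhouette
scores of the samples in the leading-PC plane under line and condition
labels.

## Survival metagene and engine

The metagene standardizes each module gene across patients, takes PC1 by
SVD, and projects patients onto it. PC sign is arbitrary, so loadings are
oriented to correlate the score positively with per-patient *mean module
expression* — meaningful because the module contains only genes upregulated
with the phenotype. Groups are the top/bottom 30% of scores (⌊0.3·n⌋ each),
with boundary ties broken by a stable sort on patient id. A consequence of
the anchoring rule worth stating: the orientation cancels the SVD sign
ambiguity and gene-order permutations (tested), but negating the *data*
flips the anchor together with the scores, so the same patient partition
reappears with the high and low labels exchanged — no orientation rule tied
to expression level can do otherwise.

Kaplan–Meier and the two-group log-rank test are the textbook estimators
(product limit; hypergeometric per-event-time variance, χ²₁ p-value). The
Cox model maximizes the Efron-corrected partial likelihood by Newton–Raphson
with step halving (gradient tolerance 1e-10); Wald standard errors come from
the inverse observed information. Efron's approximation is the accurate
default for tied event times. A constant covariate has a flat partial
likelihood: the fit returns β = 0, HR = 1 with infinite standard error
rather than raising. The test suite cross-checks all three against
lifelines — which remains a reference, never the implementation — to 1e-6.
The metagene score enters Cox as a continuous standardized covariate
(binary high/low stratification is what KM/log-rank use); subtype expands to
indicator columns against the most frequent level. Five-year analyses
administratively censor at 60 months (times clamped, events cleared).

### Synthetic cohorts

Each patient carries a latent standard-normal module-activity score *z*;
event times are exponential with hazard h₀·exp(β·z) (defaults h₀ = 0.01
events/month, β = 0.7, i.e. HR ≈ 2 per SD). Module-gene expression is
loading·z + Gaussian noise with positive loadings, so PC1 recovers *z*
(correlation > 0.99 at the default noise). Censoring is independent
exponential with its rate solved numerically so the expected censored
fraction equals `censor_rate` (default 0.3): a uniform-on-(0, T_event)
scheme would depend on the event time and bias the Cox estimate, and a fixed
administrative horizon cannot hit an arbitrary censoring fraction. The
cohort generator does not model competing risks, covariate-dependent
censoring, or cure fractions, so calibration results transfer to real
cohorts only insofar as those are absent.

## Pore images

The generator renders dark disks (intensity 0.15 of background) on a bright
background (0.8 of full scale), largest first, by rejection sampling with a
4 px margin between disks and from the border; an optional smooth
illumination ramp (0.75–1.25×) and Gaussian noise are applied on top. It
does not render fibers, so segmentation difficulty is lower than in real
reflection micrographs; the recovery tests bound geometric accuracy, not
robustness to fiber texture.

The measurement chain divides by a wide-Gaussian background estimate
(default scale 64 px, ≥ 8 px enforced; symmetric kernels reproduce linear
illumination ramps exactly away from borders), rescales to unit mean,
thresholds with Otsu (a fixed-quantile alternative is provided), labels
8-connected components, and discards border-touching components (truncated
pores) and fragments under 4 px. Pore size is the equivalent-area diameter
2√(area/π); Feret or caliper diameters would differ for non-circular pores,
and equivalent-area is the reproducible, software-independent choice.
The chain is invariant to positive intensity scaling and to rotations by
90°, and recovers planted diameters within 1 px down to 6 px disks.

## Pipeline determinism

`pipeline.run` executes stages in dependency order on explicit seeds; every
stochastic stage derives a fixed offset from the run seed. The manifest
records configuration, seeds, and sha256 hashes of all artifacts and
contains no timestamps, so identical configurations produce byte-identical
outputs (verified by hashing in tests). Problem sizes of the default run —
40 tracks per condition at 12 h of simulated tracking, a 2000-gene
triplicate design, a 400-patient cohort, one 512² image — were chosen so a
full end-to-end run takes seconds while every downstream estimate remains
comfortably inside its tested tolerance; they can be raised freely in the
configuration.

## Known limitations

- The PRW fit reports Wald-type standard errors from the weighted
  least-squares covariance; MSD points are correlated across lags, so these
  underestimate true uncertainty and are best used comparatively.
- Fold-change module discovery deliberately ignores replicate variance (no
  moderated test); it reproduces a threshold rule, not a DE model.
- The enrichment background must be supplied (or defaults to detected
  genes); no annotation hierarchy or term redundancy handling.
- The survival engine fits proportional hazards without diagnostics beyond
  convergence reporting; strong non-proportionality will go unflagged.
- Pore analysis is strictly 2D; a confocal stack must be reduced to a plane
  before analysis.
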