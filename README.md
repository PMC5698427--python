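# cinp

Analysis pipeline for the **collagen-induced network phenotype (CINP)**: the
observation that confining 3D collagen matrices (small pores, short fibers)
switch cancer cells into fast, persistent migration, multicellular network
formation, and a conserved ~70-gene transcriptional module whose expression
predicts patient survival.

The package is aimed at quantitative cell-biology and cancer-genomics groups
who track single cells in 3D matrices, profile their transcriptomes under
matrix perturbations, and ask whether the resulting gene modules carry
prognostic signal. Every stage is exercisable on synthetic data with known
ground truth, so the full chain is testable without any external downloads.

## What it computes

**Motility.** Single-cell trajectories sampled every 2 min are summarized by
instantaneous speeds, net invasion distance, and the time-averaged mean
squared displacement

    MSD(τ) = ⟨(x(t+τ) − x(t))² + (y(t+τ) − y(t))²⟩,

which is fitted with the persistent random walk (PRW) model

    MSD(τ) = 2S²P(τ − P(1 − e^(−τ/P))) + 4σ²,

yielding the cell speed *S* (μm min⁻¹), persistence time *P* (min) and static
positional error σ (μm). Groups (e.g. pre- vs post-division) are compared by
the Mann–Whitney U test.

**Expression modules.** From a TPM gene-by-sample matrix, genes detected at
mean TPM > 5 and upregulated (fold change ≥ 1.5 on replicate means) in the
high- vs low-density condition are derived per cell line and intersected:
the *common-to-cancer* module is the intersection over cancer lines minus
anything upregulated in normal cells; the *common-to-all* module is the
intersection over every line. Modules are screened for term
overrepresentation by the one-sided hypergeometric test with
Benjamini–Hochberg FDR control, with fold enrichment = observed/expected.

**Survival.** A module's activity per patient is the projection onto PC1 of
the standardized patient × gene matrix, sign-oriented so the score rises with
mean module expression. The top and bottom 30% of scores are compared by
Kaplan–Meier curves and the log-rank test; a Cox proportional-hazards
regression (Efron ties, Newton–Raphson) adjusts for age and optionally
molecular subtype, reporting HR = exp(β).

**Pore size.** Confocal-reflection matrix images are illumination-normalized,
thresholded (Otsu) so the darkest regions form a pore mask, and each interior
8-connected component is reported as its equivalent-area diameter
2·√(area/π).

**Synthetic data.** `cinp.synthgen` generates all four input kinds with
ground truth: an exactly integrated Ornstein–Uhlenbeck velocity process whose
ensemble MSD equals the PRW closed form, planted expression modules with
log-normal replicate noise, survival cohorts with a prescribed log-hazard
ratio for a latent module score, and pore images with known diameters.

## Worked example

Run every stage end-to-end on bundled synthetic fixtures:

```sh
cinp run-all --out demo --seed 0
```

which prints (abridged):

```json
{
  "motility":   {"median_P": {"low": 3.84, "high": 28.63},
                 "mannwhitney_p": 2.23e-09, "n_cells": 80},
  "expression": {"n_common_to_cancer": 70, "n_common_to_all": 35,
                 "n_enriched_terms": 1},
  "survival":   {"logrank_p": 3.65e-23, "hr_score": 1.96},
  "pores":      {"pore_count": 7, "median_diameter_px": 14.0}
}
```

Reading: cells simulated under the high-density condition fit a median
persistence time of ~29 min against ~4 min in the low-density condition
(Mann–Whitney p ≈ 2×10⁻⁹); the planted 70-gene common-to-cancer and 35-gene
common-to-all modules are recovered exactly and the planted annotation term
is flagged by enrichment; the high-metagene patient group shows worse
survival, with a Cox hazard ratio per standard deviation of score of ~2.0
(true planted value e^0.7 ≈ 2.01); and the seven synthetic pores are found at
their planted diameters. `demo/manifest.json` records parameters, seeds, and
sha256 hashes of every artifact; rerunning with the same seed reproduces the
tables byte for byte.

Individual stages are available as `cinp simulate`, `cinp motility`,
`cinp expression`, `cinp survival`, and `cinp pores` on the file formats
described in each module's docstring (trajectory CSV, TPM + metadata TSV,
clinical cohort TSV, GMT annotations, grayscale PNG/TIFF).

## Layout

| Module | Contents |
| --- | --- |
| `cinp.synthgen` | ground-truth generators for all four data kinds |
| `cinp.motility` | trajectories, MSD, PRW fitting, group statistics |
| `cinp.expression` | detection, fold-change sets, Venn modules, PCA, enrichment |
| `cinp.survival` | metagene, Kaplan–Meier, log-rank, Cox (Efron/Newton) |
| `cinp.poreimage` | illumination normalization, pore masking, diameters |
| `cinp.pipeline` / `cinp.cli` | orchestration, manifests, `cinp` CLI |
| `cinp.io` | strict readers/writers for every file dialect |

See `docs/methods.md` for the models, defaults, and design rationale.
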