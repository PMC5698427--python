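"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (a) persistent-random-walk cell trajectories whose ensemble MSD
obeys the closed form 2 S^2 P (tau - P(1 - e^(-tau/P))) + 4 sigma^2 exactly,
(b) TPM expression matrices with planted condition-responsive gene modules
shared by chosen cell-line subsets, (c) survival cohorts whose hazard depends
on a latent module-activity score with a prescribed log-hazard ratio, and
(d) fiber-matrix images carrying dark pores of known diameter.

Emulated study conditions: three cell lines (two cancer, one normal
fibroblast) in low- vs high-density collagen, biological triplicates, cells
imaged every 2 minutes for 48 hours; a 70-gene module upregulated by the
cancer lines only and a 35-gene module shared by all three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .motility import Trajectory

__all__ = [
    "PRWParams",
    "PlantedDesign",
    "SyntheticCohortSpec",
    "SyntheticTruth",
    "ExpressionDataset",
    "SurvivalCohort",
    "PlacementError",
    "simulate_prw_trajectory",
    "simulate_prw_ensemble",
    "generate_expression_dataset",
    "generate_survival_cohort",
    "generate_pore_image",
    "default_design",
]

# Study-condition defaults: 2-min sampling over 48 h; three lines, two of
# them cancer; triplicates; 70-gene common-to-cancer + 35-gene common-to-all
# planted modules.
DT_MIN = 2.0
DURATION_MIN = 48.0 * 60.0
CANCER_LINES = ("MDA", "HT1080")
NORMAL_LINES = ("HFF",)
CONDITIONS = ("low", "high")


class PlacementError(RuntimeError):
    """Raised when non-overlapping pore disks cannot be placed."""


@dataclass(frozen=True)
class PRWParams:
    """Ground-truth persistent-random-walk parameters.

    S: cell speed (um/min); P: persistence time (min); sigma: static
    positional noise per coordinate (um); dt: sampling interval (min);
    duration: tracked time (min).
    """

    S: float
    P: float
    sigma: float = 0.0
    dt: float = DT_MIN
    duration: float = DURATION_MIN

    def __post_init__(self) -> None:
        if not (self.S > 0 and self.P > 0 and self.dt > 0):
            raise ValueError("S, P and dt must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.duration < 2 * self.dt:
            raise ValueError("duration must cover at least two sampling intervals")


@dataclass(frozen=True)
class PlantedDesign:
    """Design of a planted expression experiment.

    module_spec maps a cell-line subset (tuple of labels) to
    (gene count, fold change); planted genes are upregulated by exactly that
    subset in the high condition. noise_cv is the coefficient of variation of
    the multiplicative log-normal replicate noise.
    """

    cell_lines: tuple[str, ...] = CANCER_LINES + NORMAL_LINES
    conditions: tuple[str, str] = CONDITIONS
    replicates_per_cell: int = 3
    n_genes: int = 2000
    module_spec: Mapping[tuple[str, ...], tuple[int, float]] = field(
        default_factory=lambda: {
            CANCER_LINES: (70, 2.0),
            CANCER_LINES + NORMAL_LINES: (35, 2.0),
        }
    )
    noise_cv: float = 0.1
    line_effect_cv: float = 0.5  # per-gene cell-line identity offsets
    baseline_tpm_range: tuple[float, float] = (10.0, 500.0)

    def __post_init__(self) -> None:
        if self.replicates_per_cell < 2:
            raise ValueError("need >= 2 replicates per cell line and condition")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        total = 0
        for subset, (count, fc) in self.module_spec.items():
            if not set(subset) <= set(self.cell_lines):
                raise ValueError(f"module subset {subset} not among cell lines")
            if fc <= 1:
                raise ValueError("all planted fold changes must exceed 1")
            if count < 1:
                raise ValueError("module gene counts must be positive")
            total += count
        if total > self.n_genes:
            raise ValueError(
                f"planted modules need {total} genes but design has only {self.n_genes}"
            )


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Design of a synthetic survival cohort.

    Each patient carries a latent standard-normal module-activity score; the
    event hazard is baseline_hazard * exp(beta * score) (events per month) and
    module-gene expression is loading * score + Gaussian noise.
    """

    n_patients: int = 600
    n_module_genes: int = 70
    beta: float = 0.7
    baseline_hazard: float = 0.01
    censor_rate: float = 0.3
    age_range: tuple[float, float] = (30.0, 85.0)
    expression_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 20:
            raise ValueError("n_patients must be >= 20")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.n_module_genes < 1:
            raise ValueError("need at least one module gene")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside each synthetic artifact."""

    prw_params: dict = field(default_factory=dict)
    planted_modules: dict = field(default_factory=dict)
    beta: float | None = None
    latent_scores: np.ndarray | None = None
    pore_diameters_px: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.latent_scores is not None:
            d["latent_scores"] = np.asarray(self.latent_scores).tolist()
        return d


@dataclass
class ExpressionDataset:
    """TPM matrix (genes x samples) plus per-sample metadata.

    metadata is indexed by sample id with columns cell_line, condition
    (low/high) and replicate.
    """

    tpm: pd.DataFrame
    metadata: pd.DataFrame
    transformed: bool = False  # True after z-scoring; values may then be signed

    def __post_init__(self) -> None:
        if not self.tpm.columns.equals(self.metadata.index):
            raise ValueError("tpm columns and metadata index must match")
        if self.tpm.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if not self.transformed and (self.tpm.values < 0).any():
            raise ValueError("TPM values must be nonnegative")
        for col in ("cell_line", "condition", "replicate"):
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing column {col!r}")
        counts = self.metadata.groupby(["cell_line", "condition"]).size()
        if (counts < 2).any():
            raise ValueError("every (cell_line, condition) needs >= 2 replicates")

    @property
    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.metadata["cell_line"]))


@dataclass
class SurvivalCohort:
    """Clinical table joined to module-gene expression.

    ``clinical`` has columns patient_id, time_months, event, age, stage,
    subtype; ``expression`` is patient x gene.
    """

    clinical: pd.DataFrame
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"patient_id", "time_months", "event", "age"}
        missing = req - set(self.clinical.columns)
        if missing:
            raise ValueError(f"clinical table missing columns {sorted(missing)}")
        if (self.clinical["time_months"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.clinical["event"].isin([0, 1]).all():
            raise ValueError("event flags must be 0/1")
        if len(self.expression) != len(self.clinical):
            raise ValueError("expression and clinical tables must align")
        if self.expression.isna().any().any():
            raise ValueError("module-gene expression must be complete")

    @property
    def module_genes(self) -> list[str]:
        return list(self.expression.columns)


# ---------------------------------------------------------------------------
# Persistent random walk
# ---------------------------------------------------------------------------

def _ou_step_sampler(S: float, P: float, dt: float):
    """Exact one-step sampler for the integrated OU velocity process.

    Per coordinate the velocity is a stationary Ornstein-Uhlenbeck process
    with variance S^2/2 and correlation time P; the position increment over
    dt and the end-of-step velocity are jointly Gaussian given the start
    velocity.  Sampling from that exact joint law makes the ensemble MSD
    equal the PRW closed form at every lag.
    """
    var_v = S * S / 2.0
    lam = math.exp(-dt / P)
    om = -math.expm1(-dt / P)  # 1 - lam, stable for small dt/P
    mean_x_coef = P * om  # E[dx | v0] = P(1-lam) v0
    var_x = var_v * (2.0 * P * dt - 2.0 * P * P * om) - var_v * (P * om) ** 2
    cov_xv = var_v * P * om * om
    var_v_new = var_v * (1.0 - lam * lam)
    # Cholesky of the 2x2 conditional covariance [[var_x, cov_xv], [cov_xv, var_v_new]]
    a11 = math.sqrt(max(var_x, 0.0))
    a21 = cov_xv / a11 if a11 > 0 else 0.0
    a22 = math.sqrt(max(var_v_new - a21 * a21, 0.0))
    return lam, mean_x_coef, a11, a21, a22, var_v


def _simulate_positions(params: PRWParams, n_tracks: int, rng: np.random.Generator) -> np.ndarray:
    n_steps = int(round(params.duration / params.dt))
    lam, cx, a11, a21, a22, var_v = _ou_step_sampler(params.S, params.P, params.dt)
    v = rng.normal(0.0, math.sqrt(var_v), size=(n_tracks, 2))
    pos = np.zeros((n_steps + 1, n_tracks, 2))
    z = rng.standard_normal(size=(n_steps, 2, n_tracks, 2))
    for k in range(n_steps):
        z1, z2 = z[k, 0], z[k, 1]
        dx = cx * v + a11 * z1
        v = lam * v + a21 * z1 + a22 * z2
        pos[k + 1] = pos[k] + dx
    if params.sigma > 0:
        pos = pos + rng.normal(0.0, params.sigma, size=pos.shape)
    return pos  # (n_steps+1, n_tracks, 2)


def simulate_prw_trajectory(params: PRWParams, seed: int) -> Trajectory:
    """Simulate one PRW track sampled at dt intervals (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    pos = _simulate_positions(params, 1, rng)
    times = np.arange(pos.shape[0]) * params.dt
    return Trajectory("prw", times, pos[:, 0, 0], pos[:, 0, 1])


def simulate_prw_ensemble(params: PRWParams, n_tracks: int, seed: int) -> list[Trajectory]:
    """Simulate an ensemble of independent PRW tracks under one parameter set."""
    rng = np.random.default_rng(seed)
    pos = _simulate_positions(params, n_tracks, rng)
    times = np.arange(pos.shape[0]) * params.dt
    return [
        Trajectory(f"prw_{i:04d}", times, pos[:, i, 0], pos[:, i, 1])
        for i in range(n_tracks)
    ]


# ---------------------------------------------------------------------------
# Planted expression datasets
# ---------------------------------------------------------------------------

def default_design(**overrides) -> PlantedDesign:
    """The study-condition design: 3 lines x 2 conditions x 3 replicates,
    2000 genes, a 70-gene common-to-cancer and a 35-gene common-to-all module
    at fold change 2."""
    return PlantedDesign(**overrides)


def generate_expression_dataset(
    design: PlantedDesign, seed: int
) -> tuple[ExpressionDataset, SyntheticTruth]:
    """Generate a TPM matrix with planted condition-responsive modules.

    Planted genes have a high/low condition mean ratio equal to the specified
    fold change in exactly the specified cell-line subset; replicate noise is
    multiplicative log-normal with unit mean and CV = noise_cv, so at
    noise_cv = 0 the realized ratios equal the planted fold changes exactly.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(design.n_genes)]
    lo, hi = design.baseline_tpm_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=design.n_genes))
    # cell-line identity: per-gene multiplicative offsets shared by both
    # conditions within a line, so they dominate raw variance (as cell type
    # does in real data) but cancel exactly in within-line fold changes
    line_base: dict[str, np.ndarray] = {}
    for line in design.cell_lines:
        if design.line_effect_cv > 0:
            s2l = math.log(1.0 + design.line_effect_cv**2)
            factor = np.exp(rng.normal(-s2l / 2.0, math.sqrt(s2l), size=design.n_genes))
        else:
            factor = np.ones(design.n_genes)
        line_base[line] = baseline * factor

    # fold-change multiplier per (gene, line, condition)
    planted: dict[str, list[str]] = {}
    fc_mult = {
        (line, cond): np.ones(design.n_genes)
        for line in design.cell_lines
        for cond in design.conditions
    }
    cursor = 0
    high = design.conditions[1]
    for subset, (count, fc) in design.module_spec.items():
        idx = np.arange(cursor, cursor + count)
        cursor += count
        planted["+".join(subset)] = [genes[i] for i in idx]
        for line in subset:
            fc_mult[(line, high)][idx] *= fc

    if design.noise_cv > 0:
        s2 = math.log(1.0 + design.noise_cv**2)
        mu, sd = -s2 / 2.0, math.sqrt(s2)
    cols, col_meta = [], []
    data = {}
    for line in design.cell_lines:
        for cond in design.conditions:
            for rep in range(1, design.replicates_per_cell + 1):
                sid = f"{line}_{cond}_r{rep}"
                mean = line_base[line] * fc_mult[(line, cond)]
                if design.noise_cv > 0:
                    noise = np.exp(rng.normal(mu, sd, size=design.n_genes))
                    vals = mean * noise
                else:
                    vals = mean
                data[sid] = vals
                cols.append(sid)
                col_meta.append({"sample": sid, "cell_line": line,
                                 "condition": cond, "replicate": rep})
    tpm = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=cols)
    meta = pd.DataFrame(col_meta).set_index("sample")
    truth = SyntheticTruth(planted_modules=planted)
    return ExpressionDataset(tpm=tpm, metadata=meta), truth


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

def _censoring_rate_for(hazards: np.ndarray, censor_rate: float) -> float:
    """Exponential-censoring rate giving the target expected censored fraction.

    With event time ~ Exp(h_i) and independent censoring ~ Exp(c), patient i
    is censored with probability c / (c + h_i); solve the cohort mean for c.
    """
    if censor_rate == 0:
        return 0.0

    def frac(c: float) -> float:
        return float(np.mean(c / (c + hazards))) - censor_rate

    hi = float(hazards.max())
    upper = hi * censor_rate / (1 - censor_rate) * 10 + hi
    while frac(upper) < 0:
        upper *= 10
    return float(optimize.brentq(frac, 1e-12, upper))


def generate_survival_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[SurvivalCohort, SyntheticTruth]:
    """Generate a cohort whose hazard depends on a latent module score.

    Event times are exponential with hazard baseline * exp(beta * score);
    censoring is independent exponential, calibrated so the expected censored
    fraction equals censor_rate.  Module-gene expression is
    loading * score + N(0, expression_noise_sd) with positive per-gene
    loadings, so the module's first principal component recovers the latent
    score.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    score = rng.standard_normal(n)
    hazards = spec.baseline_hazard * np.exp(spec.beta * score)
    event_time = rng.exponential(1.0 / hazards)
    c_rate = _censoring_rate_for(hazards, spec.censor_rate)
    if c_rate > 0:
        censor_time = rng.exponential(1.0 / c_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-6)  # strictly positive survival times

    loadings = rng.uniform(0.5, 1.5, size=spec.n_module_genes)
    expr = np.outer(score, loadings) + rng.normal(
        0.0, spec.expression_noise_sd, size=(n, spec.n_module_genes)
    )
    gene_cols = [f"MG{i:03d}" for i in range(spec.n_module_genes)]
    patient_ids = [f"P{i:04d}" for i in range(n)]
    clinical = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "time_months": time,
            "event": event,
            "age": rng.uniform(*spec.age_range, size=n).round(1),
            "stage": "I",
            "subtype": rng.choice(["LumA", "LumB", "TN", "HER2"], size=n),
        }
    )
    expression = pd.DataFrame(expr, columns=gene_cols, index=clinical.index)
    truth = SyntheticTruth(beta=spec.beta, latent_scores=score)
    return SurvivalCohort(clinical=clinical, expression=expression), truth


# ---------------------------------------------------------------------------
# Pore images
# ---------------------------------------------------------------------------

def generate_pore_image(
    diameters_px: Sequence[float],
    image_size: int = 512,
    background_level: float = 0.8,
    noise_sd: float = 0.0,
    gradient: bool = False,
    pore_level: float = 0.15,
    seed: int = 0,
    max_tries: int = 5000,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Render a bright fiber-background image with dark non-overlapping pores.

    Disks of the given diameters (>= 3 px) are placed away from the border
    with a small margin; an optional smooth illumination gradient and
    Gaussian noise are applied on top.  Raises PlacementError if a disk
    cannot be placed within ``max_tries`` attempts.
    """
    diameters = [float(d) for d in diameters_px]
    if any(d < 3 for d in diameters):
        raise ValueError("pore diameters must be >= 3 px")
    rng = np.random.default_rng(seed)
    img = np.full((image_size, image_size), background_level, dtype=float)
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    margin = 4.0
    placed: list[tuple[float, float, float]] = []  # (cy, cx, r)
    for d in sorted(diameters, reverse=True):  # largest first eases packing
        r = d / 2.0
        for _ in range(max_tries):
            cy = rng.uniform(r + margin, image_size - r - margin)
            cx = rng.uniform(r + margin, image_size - r - margin)
            if all((cy - py) ** 2 + (cx - px) ** 2 >= (r + pr + margin) ** 2
                   for py, px, pr in placed):
                placed.append((cy, cx, r))
                break
        else:
            raise PlacementError(
                f"could not place a {d:.0f} px pore after {max_tries} tries"
            )
        mask = (yy - placed[-1][0]) ** 2 + (xx - placed[-1][1]) ** 2 <= r * r
        img[mask] = pore_level * background_level
    if gradient:
        ramp = np.linspace(0.75, 1.25, image_size)
        img = img * ramp[None, :] * ramp[:, None] ** 0.5
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    truth = SyntheticTruth(pore_diameters_px=sorted(diameters))
    return img, truth
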