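"""File dialects: trajectory CSV, TPM/metadata/cohort TSV, GMT, gene lists,
grayscale images — with strict, line-numbered validation.

Dialects
--------
trajectories : CSV with columns cell_id, t_min, x_um, y_um (one row per frame).
expression   : TSV gene x sample, first column "gene"; sidecar metadata TSV
               with columns sample, cell_line, condition, replicate.
cohort       : TSV with patient_id, time_months, event, age, stage, subtype,
               then one column per module gene.
gene list    : plain text, one gene per line.
annotation   : GMT (term <tab> description <tab> gene...).
images       : 8/16-bit grayscale PNG/TIFF via imageio.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .expression import AnnotationMap
from .motility import Trajectory
from .synthgen import ExpressionDataset, SurvivalCohort

__all__ = [
    "SchemaError",
    "read_trajectories", "write_trajectories",
    "read_expression", "write_expression",
    "read_cohort", "write_cohort",
    "read_gene_list", "write_gene_list",
    "read_gmt", "write_gmt",
    "read_image", "write_image",
]

MAX_VIOLATIONS = 5


class SchemaError(ValueError):
    """Malformed input file; carries up to the first five violations."""

    def __init__(self, path, violations: list[str]):
        self.path = str(path)
        self.violations = violations[:MAX_VIOLATIONS]
        lines = "\n  ".join(self.violations)
        super().__init__(f"{self.path}: invalid file\n  {lines}")


def _fail_if(violations: list[str], path) -> None:
    if violations:
        raise SchemaError(path, violations)


# -- trajectories -----------------------------------------------------------

def write_trajectories(trajectories: Iterable[Trajectory], path) -> None:
    frames = []
    for traj in trajectories:
        frames.append(pd.DataFrame({
            "cell_id": traj.cell_id, "t_min": traj.times,
            "x_um": traj.x, "y_um": traj.y,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_trajectories(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    violations: list[str] = []
    required = ["cell_id", "t_min", "x_um", "y_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(path, [f"missing columns: {missing}"])
    for col in ("t_min", "x_um", "y_um"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        for i in bad[:MAX_VIOLATIONS]:
            violations.append(f"line {i + 2}: non-numeric {col}: {df.loc[i, col]!r}")
    _fail_if(violations, path)
    out = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        t = sub["t_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            k = int(np.flatnonzero(np.diff(t) <= 0)[0])
            violations.append(
                f"cell {cell_id!r}: non-monotone timestamps at row {int(sub.index[k]) + 2}"
            )
            continue
        try:
            out.append(Trajectory(str(cell_id), t, sub["x_um"].to_numpy(), sub["y_um"].to_numpy()))
        except ValueError as exc:
            violations.append(str(exc))
    _fail_if(violations, path)
    return out


# -- expression -------------------------------------------------------------

def write_expression(ds: ExpressionDataset, tpm_path, meta_path) -> None:
    ds.tpm.to_csv(tpm_path, sep="\t", index_label="gene", float_format="%.6f")
    ds.metadata.to_csv(meta_path, sep="\t", index_label="sample")


def read_expression(tpm_path, meta_path) -> ExpressionDataset:
    tpm = pd.read_csv(tpm_path, sep="\t", index_col="gene")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    violations: list[str] = []
    neg = np.argwhere(tpm.values < 0)
    for r, c in neg[:MAX_VIOLATIONS]:
        violations.append(
            f"line {r + 2}: negative TPM for gene {tpm.index[r]!r} in sample {tpm.columns[c]!r}"
        )
    for col in ("cell_line", "condition", "replicate"):
        if col not in meta.columns:
            violations.append(f"metadata missing column {col!r}")
    _fail_if(violations, tpm_path)
    if "condition" in meta.columns:
        bad = meta.index[~meta["condition"].isin(["low", "high"])]
        for sid in bad[:MAX_VIOLATIONS]:
            violations.append(f"sample {sid!r}: condition must be low/high")
    unknown = [s for s in tpm.columns if s not in meta.index]
    if unknown:
        violations.append(f"samples without metadata: {unknown[:MAX_VIOLATIONS]}")
    _fail_if(violations, meta_path)
    return ExpressionDataset(tpm=tpm, metadata=meta.loc[tpm.columns])


# -- survival cohorts -------------------------------------------------------

CLINICAL_COLS = ["patient_id", "time_months", "event", "age", "stage", "subtype"]


def write_cohort(cohort: SurvivalCohort, path) -> None:
    joined = pd.concat(
        [cohort.clinical[CLINICAL_COLS].reset_index(drop=True),
         cohort.expression.reset_index(drop=True)],
        axis=1,
    )
    joined.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_cohort(path) -> SurvivalCohort:
    df = pd.read_csv(path, sep="\t")
    violations: list[str] = []
    missing = [c for c in CLINICAL_COLS if c not in df.columns]
    if missing:
        raise SchemaError(path, [f"missing columns: {missing}"])
    bad_t = df.index[~(pd.to_numeric(df["time_months"], errors="coerce") > 0)]
    for i in bad_t[:MAX_VIOLATIONS]:
        violations.append(f"line {i + 2}: time_months must be positive")
    bad_e = df.index[~df["event"].isin([0, 1])]
    for i in bad_e[:MAX_VIOLATIONS]:
        violations.append(f"line {i + 2}: event must be 0/1")
    _fail_if(violations, path)
    gene_cols = [c for c in df.columns if c not in CLINICAL_COLS]
    return SurvivalCohort(clinical=df[CLINICAL_COLS], expression=df[gene_cols])


# -- gene lists and GMT -----------------------------------------------------

def write_gene_list(genes: Iterable[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def write_gmt(annotation: AnnotationMap, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotation.terms):
            desc = annotation.descriptions.get(term, "")
            genes = "\t".join(sorted(annotation.terms[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def read_gmt(path, universe: Iterable[str] | None = None) -> AnnotationMap:
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    violations: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            violations.append(f"line {lineno}: GMT rows need term, description, >= 1 gene")
            continue
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term in terms:
            violations.append(f"line {lineno}: duplicate term {term!r}")
            continue
        terms[term] = frozenset(genes)
        descriptions[term] = desc
    _fail_if(violations, path)
    all_genes = frozenset().union(*terms.values()) if terms else frozenset()
    uni = frozenset(universe) | all_genes if universe is not None else all_genes
    return AnnotationMap(terms=terms, descriptions=descriptions, universe=uni)


# -- images -----------------------------------------------------------------

def write_image(pixels: np.ndarray, path) -> None:
    """Write a float image in [0, ~1.2] as 16-bit grayscale PNG/TIFF."""
    px = np.asarray(pixels, dtype=float)
    hi = px.max() if px.max() > 0 else 1.0
    scaled = np.clip(px / hi, 0, 1)
    iio.imwrite(path, (scaled * 65535).astype(np.uint16))


def read_image(path, pixel_size: float | None = None):
    from .poreimage import PoreImage

    raw = np.asarray(iio.imread(path), dtype=float)
    if raw.ndim == 3:  # collapse any color/alpha channels
        raw = raw.mean(axis=-1)
    return PoreImage(pixels=raw / raw.max() if raw.max() > 0 else raw, pixel_size=pixel_size)
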