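"""Conserved gene-module discovery from TPM matrices, with enrichment.

Per cell line, genes upregulated in the high- vs low-density collagen
condition (replicate-mean TPM fold change >= threshold, default 1.5) are
intersected across lines: the "common-to-cancer" module is the intersection
of the cancer lines' sets minus anything upregulated in a normal line, and
the "common-to-all" module is the intersection across all lines.  Modules
are tested for term overrepresentation with a one-sided hypergeometric test
and Benjamini-Hochberg FDR correction against a user-supplied flat
annotation map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .synthgen import ExpressionDataset

__all__ = [
    "DEGSets",
    "VennPartition",
    "AnnotationMap",
    "PCAReport",
    "DETECTION_TPM",
    "detect_genes",
    "upregulated_set",
    "degsets_for_all_lines",
    "venn_modules",
    "zscore_by_cell_type",
    "pca_condition_check",
    "threshold_sensitivity",
    "enrich",
]

DETECTION_TPM = 5.0  # a gene counts as detected if mean TPM across samples > 5


@dataclass(frozen=True)
class DEGSets:
    """Per-cell-line sets of genes upregulated at a fold-change threshold."""

    sets: Mapping[str, frozenset[str]]
    fc_threshold: float
    pseudocount: float

    def __getitem__(self, line: str) -> frozenset[str]:
        return self.sets[line]


@dataclass(frozen=True)
class VennPartition:
    """Venn blocks of the per-line upregulated sets.

    ``common_to_cancer`` = intersection of cancer-line sets minus the union
    of normal-line sets; ``common_to_all`` = intersection across every line.
    ``blocks`` maps each nonempty membership pattern (tuple of member lines)
    to its exclusive gene set; blocks are pairwise disjoint and their union
    is the union of the input sets.
    """

    common_to_cancer: frozenset[str]
    common_to_all: frozenset[str]
    blocks: Mapping[tuple[str, ...], frozenset[str]]

    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.blocks.items()}


@dataclass
class AnnotationMap:
    """Flat term -> gene-set annotation with a background universe."""

    terms: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.terms = {t: frozenset(g) for t, g in self.terms.items()}
        if not self.universe:
            self.universe = frozenset().union(*self.terms.values()) if self.terms else frozenset()
        else:
            self.universe = frozenset(self.universe)
        for term, genes in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {term!r} annotates genes outside the universe")


@dataclass(frozen=True)
class PCAReport:
    """Sample PC coordinates with variance-explained and group separation."""

    scores: pd.DataFrame  # samples x PCs
    variance_explained: np.ndarray
    silhouette_by_cell_line: float
    silhouette_by_condition: float


def detect_genes(ds: ExpressionDataset, min_tpm: float = DETECTION_TPM) -> frozenset[str]:
    """Genes whose mean TPM across all samples exceeds ``min_tpm`` (strict >)."""
    means = ds.tpm.mean(axis=1)
    return frozenset(means.index[means > min_tpm])


def _condition_means(ds: ExpressionDataset, cell_line: str) -> tuple[pd.Series, pd.Series]:
    meta = ds.metadata
    if cell_line not in set(meta["cell_line"]):
        raise KeyError(f"unknown cell line {cell_line!r}")
    out = []
    for cond in ("low", "high"):
        cols = meta.index[(meta["cell_line"] == cell_line) & (meta["condition"] == cond)]
        if len(cols) == 0:
            raise ValueError(f"cell line {cell_line!r} has no {cond!r}-condition samples")
        out.append(ds.tpm[cols].mean(axis=1))
    return out[0], out[1]


def upregulated_set(
    ds: ExpressionDataset,
    cell_line: str,
    fc_threshold: float = 1.5,
    pseudocount: float = 1.0,
    detected: Iterable[str] | None = None,
) -> frozenset[str]:
    """Detected genes with (mean_high + c) / (mean_low + c) >= fc_threshold.

    Fold change is computed on replicate-mean TPM for the given cell line;
    the pseudocount keeps the ratio finite when the low-condition mean is 0.
    The boundary is inclusive (a gene at exactly the threshold is kept).
    """
    if fc_threshold <= 1:
        raise ValueError("fc_threshold must exceed 1")
    if detected is None:
        detected = detect_genes(ds)
    low, high = _condition_means(ds, cell_line)
    ratio = (high + pseudocount) / (low + pseudocount)
    up = frozenset(ratio.index[ratio >= fc_threshold])
    return up & frozenset(detected)


def degsets_for_all_lines(
    ds: ExpressionDataset, fc_threshold: float = 1.5, pseudocount: float = 1.0
) -> DEGSets:
    """Upregulated set for every cell line, sharing one detection filter."""
    detected = detect_genes(ds)
    sets = {
        line: upregulated_set(ds, line, fc_threshold, pseudocount, detected)
        for line in ds.cell_lines
    }
    return DEGSets(sets=sets, fc_threshold=fc_threshold, pseudocount=pseudocount)


def venn_modules(
    sets: DEGSets | Mapping[str, Iterable[str]],
    cancer_lines: Sequence[str],
    normal_lines: Sequence[str],
) -> VennPartition:
    """Intersect per-line upregulated sets into conserved modules.

    common_to_cancer = (intersection over cancer lines) minus (union over
    normal lines); common_to_all = intersection over every line.  All Venn
    membership blocks are emitted alongside.
    """
    mapping = sets.sets if isinstance(sets, DEGSets) else sets
    mapping = {k: frozenset(v) for k, v in mapping.items()}
    if len(cancer_lines) < 2 or len(normal_lines) < 1:
        raise ValueError("need >= 2 cancer lines and >= 1 normal line")
    for label in list(cancer_lines) + list(normal_lines):
        if label not in mapping:
            raise KeyError(f"unknown line label {label!r}")
    cancer_common = frozenset.intersection(*(mapping[c] for c in cancer_lines))
    normal_union = frozenset().union(*(mapping[nl] for nl in normal_lines))
    all_lines = list(cancer_lines) + list(normal_lines)
    common_all = frozenset.intersection(*(mapping[line] for line in all_lines))

    blocks: dict[tuple[str, ...], frozenset[str]] = {}
    for r in range(1, len(all_lines) + 1):
        for members in combinations(all_lines, r):
            inside = frozenset.intersection(*(mapping[m] for m in members))
            outside = frozenset().union(
                *(mapping[m] for m in all_lines if m not in members), frozenset()
            )
            block = inside - outside
            if block:
                blocks[members] = block
    return VennPartition(
        common_to_cancer=cancer_common - normal_union,
        common_to_all=common_all,
        blocks=blocks,
    )


def zscore_by_cell_type(ds: ExpressionDataset) -> ExpressionDataset:
    """Z-score each gene within each cell line (across that line's samples).

    Removes the dominant cell-line offsets so that the culture condition
    carries the remaining variance; genes with zero variance within a line
    map to 0 rather than NaN.
    """
    out = ds.tpm.copy().astype(float)
    for line in ds.cell_lines:
        cols = ds.metadata.index[ds.metadata["cell_line"] == line]
        block = out[cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=0)
        z = block.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
        out[cols] = z
    return ExpressionDataset(tpm=out, metadata=ds.metadata, transformed=True)


def pca_condition_check(ds: ExpressionDataset, n_components: int = 5) -> PCAReport:
    """PCA of the gene-centered matrix with grouping-separation summary.

    On raw TPM the leading component separates cell lines; after the
    per-line z-score transform it separates culture conditions.  Separation
    is summarized as the silhouette score of the samples in the leading-PC
    plane under each labelling.
    """
    X = ds.tpm.values.T.astype(float)  # samples x genes
    if X.shape[0] < 3:
        raise ValueError("need >= 3 samples for PCA")
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    var_frac = var / var.sum() if var.sum() > 0 else var
    k = min(n_components, s.size)
    scores = pd.DataFrame(
        u[:, :k] * s[:k],
        index=ds.tpm.columns,
        columns=[f"PC{i+1}" for i in range(k)],
    )
    plane = scores.values[:, : min(2, k)]

    def _sil(labels: pd.Series) -> float:
        labs = labels.values
        if len(set(labs)) < 2:
            return float("nan")
        return float(silhouette_score(plane, labs))

    return PCAReport(
        scores=scores,
        variance_explained=var_frac,
        silhouette_by_cell_line=_sil(ds.metadata["cell_line"]),
        silhouette_by_condition=_sil(ds.metadata["condition"]),
    )


def _jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def threshold_sensitivity(
    ds: ExpressionDataset,
    cancer_lines: Sequence[str],
    normal_lines: Sequence[str],
    thresholds: Sequence[float] = tuple(np.round(np.arange(1.3, 1.95, 0.1), 2)),
    reference_threshold: float = 1.5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Module size and Jaccard overlap vs the reference threshold's modules.

    Sweeps the upregulation fold-change threshold (default 1.3..1.9) and
    reports, per threshold, the sizes of the common-to-cancer and
    common-to-all modules and their Jaccard similarity to the modules at the
    reference threshold (default 1.5).
    """
    ref = venn_modules(
        degsets_for_all_lines(ds, reference_threshold, pseudocount), cancer_lines, normal_lines
    )
    rows = []
    for thr in thresholds:
        part = venn_modules(
            degsets_for_all_lines(ds, float(thr), pseudocount), cancer_lines, normal_lines
        )
        rows.append(
            {
                "threshold": float(thr),
                "n_common_to_cancer": len(part.common_to_cancer),
                "n_common_to_all": len(part.common_to_all),
                "jaccard_common_to_cancer": _jaccard(part.common_to_cancer, ref.common_to_cancer),
                "jaccard_common_to_all": _jaccard(part.common_to_all, ref.common_to_all),
            }
        )
    return pd.DataFrame(rows)


def enrich(
    module: Iterable[str],
    annotation: AnnotationMap,
    alpha: float = 0.05,
    background: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of annotation terms in a module.

    For each term with K background genes, drawing n = |module| genes from a
    universe of N, the one-sided upper-tail p is P(X >= k) for k observed
    term genes; the expected count is n*K/N and fold_enrichment = k / (n*K/N).
    BH adjustment is applied across all tested terms; rows with fdr <= alpha
    are flagged significant.  Terms with no background genes are skipped with
    a warning.
    """
    bg = frozenset(background) if background is not None else annotation.universe
    mod = frozenset(module)
    if not mod <= bg:
        raise ValueError("module genes must all lie in the background universe")
    N, n = len(bg), len(mod)
    rows = []
    for term, genes in annotation.terms.items():
        K = len(genes & bg)
        if K == 0:
            warnings.warn(f"term {term!r} has no background genes; skipped")
            continue
        k = len(genes & mod)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        expected = n * K / N
        rows.append(
            {
                "term": term,
                "description": annotation.descriptions.get(term, ""),
                "observed": k,
                "expected": expected,
                "fold_enrichment": k / expected,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        df["fdr"] = []
        df["significant"] = []
        return df
    _, fdr, _, _ = multipletests(df["p"].values, method="fdr_bh")
    df["fdr"] = fdr
    df["significant"] = df["fdr"] <= alpha
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
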