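"""Module discovery, z-score/PCA structure, and enrichment against oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cinp import synthgen
from cinp.expression import (
    AnnotationMap,
    degsets_for_all_lines,
    detect_genes,
    enrich,
    pca_condition_check,
    threshold_sensitivity,
    upregulated_set,
    venn_modules,
    zscore_by_cell_type,
)
from cinp.synthgen import ExpressionDataset


def tiny_dataset(values: np.ndarray, lines=("A", "B"), reps=2) -> ExpressionDataset:
    """gene x sample dataset with metadata from a (genes x samples) array."""
    cols, meta = [], []
    i = 0
    for line in lines:
        for cond in ("low", "high"):
            for r in range(1, reps + 1):
                sid = f"{line}_{cond}_r{r}"
                cols.append(sid)
                meta.append({"sample": sid, "cell_line": line, "condition": cond,
                             "replicate": r})
                i += 1
    tpm = pd.DataFrame(values, columns=cols,
                       index=[f"g{j}" for j in range(values.shape[0])])
    return ExpressionDataset(tpm=tpm, metadata=pd.DataFrame(meta).set_index("sample"))


class TestDetectGenes:
    def test_strict_boundary(self):
        vals = np.full((2, 8), 5.0)
        vals[1] = 5.01
        ds = tiny_dataset(vals)
        detected = detect_genes(ds)
        assert "g0" not in detected and "g1" in detected

    def test_matches_brute_force_row_means(self, rng):
        vals = rng.uniform(0, 20, size=(50, 8))
        ds = tiny_dataset(vals)
        expected = {f"g{i}" for i in range(50) if vals[i].mean() > 5.0}
        assert detect_genes(ds) == expected


class TestUpregulatedSet:
    def test_zero_noise_planted_roundtrip(self, zero_noise_dataset):
        ds, truth = zero_noise_dataset
        planted = set(truth.planted_modules["MDA+HT1080"]) | set(
            truth.planted_modules["MDA+HT1080+HFF"]
        )
        got = upregulated_set(ds, "MDA", fc_threshold=1.5)
        assert got == planted

    def test_boundary_ratio_included(self):
        vals = np.ones((1, 8)) * 10.0
        vals[0, [1, 3]] = 10.0  # low condition replicates stay 10
        ds = tiny_dataset(vals)
        # craft exact ratio 1.5 with pseudocount 0: high mean 15, low mean 10
        tpm = ds.tpm.copy()
        high_cols = ds.metadata.index[ds.metadata.condition == "high"]
        tpm.loc["g0", high_cols] = 15.0
        ds2 = ExpressionDataset(tpm=tpm, metadata=ds.metadata)
        assert "g0" in upregulated_set(ds2, "A", fc_threshold=1.5, pseudocount=0.0)

    def test_pseudocount_handles_zero_low_mean(self):
        vals = np.zeros((1, 8))
        high_cols_mask = [c for c in range(8)]
        ds = tiny_dataset(np.full((1, 8), 0.0))
        tpm = ds.tpm.copy()
        tpm.loc["g0", ds.metadata.index[ds.metadata.condition == "high"]] = 30.0
        ds2 = ExpressionDataset(tpm=tpm, metadata=ds.metadata)
        got = upregulated_set(ds2, "A", fc_threshold=1.5, pseudocount=1.0)
        assert "g0" in got  # (15+1)/(0+1) = 16, finite and above threshold

    def test_unknown_line_raises(self, zero_noise_dataset):
        with pytest.raises(KeyError):
            upregulated_set(zero_noise_dataset[0], "nope")

    def test_monotone_in_threshold(self, rng):
        ds, _ = synthgen.generate_expression_dataset(
            synthgen.default_design(n_genes=300), seed=17
        )
        prev = None
        for thr in (1.3, 1.5, 1.7, 1.9):
            cur = upregulated_set(ds, "MDA", fc_threshold=thr)
            if prev is not None:
                assert cur <= prev
            prev = cur


class TestVennModules:
    def test_toy_set_algebra(self):
        sets = {"A": {1, 2, 3}, "B": {2, 3, 4}, "HFF": {3}}
        part = venn_modules(sets, ["A", "B"], ["HFF"])
        assert part.common_to_cancer == {2}
        assert part.common_to_all == {3}

    def test_disjoint_sets_give_empty_modules(self):
        part = venn_modules({"A": {1}, "B": {2}, "N": {3}}, ["A", "B"], ["N"])
        assert not part.common_to_cancer and not part.common_to_all

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            venn_modules({"A": {1}, "B": {2}}, ["A", "B"], ["missing"])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        sets = {
            line: set(rng.choice(40, size=rng.integers(0, 20), replace=False).tolist())
            for line in ("A", "B", "N")
        }
        part = venn_modules(sets, ["A", "B"], ["N"])
        blocks = list(part.blocks.values())
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                assert not (blocks[i] & blocks[j])
        union = set().union(*blocks) if blocks else set()
        assert union == sets["A"] | sets["B"] | sets["N"]
        # each input set is reconstructed from the blocks containing its label
        for line in sets:
            rebuilt = set().union(
                *(b for members, b in part.blocks.items() if line in members),
                set(),
            )
            assert rebuilt == sets[line]

    def test_planted_modules_recovered_exactly(self, zero_noise_dataset):
        ds, truth = zero_noise_dataset
        part = venn_modules(degsets_for_all_lines(ds), ["MDA", "HT1080"], ["HFF"])
        assert part.common_to_cancer == frozenset(truth.planted_modules["MDA+HT1080"])
        assert part.common_to_all == frozenset(
            truth.planted_modules["MDA+HT1080+HFF"]
        )


class TestZScore:
    def test_per_line_mean_zero_sd_one(self, rng):
        vals = rng.uniform(1, 100, size=(30, 8))
        ds = tiny_dataset(vals)
        z = zscore_by_cell_type(ds)
        for line in ("A", "B"):
            cols = z.metadata.index[z.metadata.cell_line == line]
            block = z.tpm[cols].values
            np.testing.assert_allclose(block.mean(axis=1), 0.0, atol=1e-12)
            sd = block.std(axis=1)
            np.testing.assert_allclose(sd[sd > 0], 1.0)

    def test_constant_gene_maps_to_zero(self):
        vals = np.ones((1, 8)) * 7.0
        z = zscore_by_cell_type(tiny_dataset(vals))
        np.testing.assert_array_equal(z.tpm.values, 0.0)

    def test_matches_hand_computed_toy(self):
        vals = np.array([[1.0, 2.0, 3.0, 4.0]])
        ds = tiny_dataset(vals, lines=("A",), reps=2)
        z = zscore_by_cell_type(ds)
        expected = (vals[0] - 2.5) / np.std(vals[0])
        np.testing.assert_allclose(z.tpm.values[0], expected)


class TestPCA:
    def test_variance_fractions_sum_to_one(self, rng):
        ds = tiny_dataset(rng.uniform(1, 50, size=(40, 8)))
        rep = pca_condition_check(ds)
        assert rep.variance_explained.sum() == pytest.approx(1.0)

    def test_condition_emerges_after_zscore(self):
        ds, _ = synthgen.generate_expression_dataset(
            synthgen.default_design(), seed=23
        )
        raw = pca_condition_check(ds)
        trans = pca_condition_check(zscore_by_cell_type(ds))
        # raw: cell-line offsets dominate; transformed: condition separates
        assert raw.silhouette_by_cell_line > raw.silhouette_by_condition
        assert trans.silhouette_by_condition > 0.2
        assert trans.silhouette_by_condition > trans.silhouette_by_cell_line

    def test_duplicate_samples_have_zero_pc_distance(self, rng):
        vals = rng.uniform(1, 50, size=(30, 8))
        vals[:, 1] = vals[:, 0]
        rep = pca_condition_check(tiny_dataset(vals))
        d = np.linalg.norm(rep.scores.iloc[0] - rep.scores.iloc[1])
        assert d == pytest.approx(0.0, abs=1e-9)


class TestThresholdSensitivity:
    def test_zero_noise_invariant_below_planted_fc(self, zero_noise_dataset):
        # pseudocount 0 keeps the constructed ratios at exactly 2.0, so the
        # module is identical at every threshold below the planted fc
        ds, _ = zero_noise_dataset
        table = threshold_sensitivity(ds, ["MDA", "HT1080"], ["HFF"], pseudocount=0.0)
        assert (table["n_common_to_cancer"] == 70).all()
        assert (table["jaccard_common_to_cancer"] == 1.0).all()

    def test_threshold_above_all_fcs_empties_modules(self, zero_noise_dataset):
        ds, _ = zero_noise_dataset
        table = threshold_sensitivity(
            ds, ["MDA", "HT1080"], ["HFF"], thresholds=(2.5, 3.0)
        )
        assert (table["n_common_to_cancer"] == 0).all()

    def test_sizes_monotone_in_threshold(self):
        ds, _ = synthgen.generate_expression_dataset(
            synthgen.default_design(noise_cv=0.3), seed=31
        )
        table = threshold_sensitivity(ds, ["MDA", "HT1080"], ["HFF"])
        assert (np.diff(table["n_common_to_cancer"]) <= 0).all()
        assert (np.diff(table["n_common_to_all"]) <= 0).all()


def exact_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exhaustive summation oracle for P(X >= k)."""
    total = 0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / math.comb(N, n)


class TestEnrich:
    def annotation(self, universe_size=20, term_genes=5):
        genes = [f"g{i}" for i in range(universe_size)]
        return (
            AnnotationMap(
                terms={"T": frozenset(genes[:term_genes])},
                universe=frozenset(genes),
            ),
            genes,
        )

    def test_fully_enriched_module_exact_p(self):
        ann, genes = self.annotation()
        table = enrich(genes[:5], ann)
        assert table["p"].iloc[0] == pytest.approx(1 / 15504, rel=1e-12)

    def test_zero_observed_gives_p_one(self):
        ann, genes = self.annotation()
        table = enrich(genes[10:15], ann)
        assert table["p"].iloc[0] == pytest.approx(1.0)

    def test_fold_enrichment_formula(self):
        genes = [f"g{i}" for i in range(100)]
        ann = AnnotationMap(
            terms={"T": frozenset(genes[:10])}, universe=frozenset(genes)
        )
        module = genes[:4] + genes[50:56]  # 10 genes, 4 in term
        table = enrich(module, ann)
        assert table["expected"].iloc[0] == pytest.approx(1.0)
        assert table["fold_enrichment"].iloc[0] == pytest.approx(4.0)

    def test_p_matches_combinatorial_oracle(self, rng):
        for _ in range(50):
            N = int(rng.integers(5, 30))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            genes = [f"g{i}" for i in range(N)]
            term = set(rng.choice(genes, size=K, replace=False).tolist())
            module = set(rng.choice(genes, size=n, replace=False).tolist())
            ann = AnnotationMap(terms={"T": frozenset(term)}, universe=frozenset(genes))
            table = enrich(module, ann)
            k = len(term & module)
            assert table["p"].iloc[0] == pytest.approx(
                exact_hypergeom_upper_tail(N, K, n, k), rel=1e-10
            )

    def test_module_outside_universe_rejected(self):
        ann, genes = self.annotation()
        with pytest.raises(ValueError):
            enrich(["not_a_gene"], ann)

    def test_empty_term_skipped_with_warning(self):
        genes = [f"g{i}" for i in range(10)]
        ann = AnnotationMap(
            terms={"T": frozenset(genes[:3]), "empty": frozenset()},
            universe=frozenset(genes),
        )
        with pytest.warns(UserWarning, match="empty"):
            table = enrich(genes[:3], ann)
        assert list(table["term"]) == ["T"]


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up adjusted values."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBHAdjustment:
    def test_matches_stepup_oracle_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            _, fdr, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(fdr, bh_stepup_oracle(p), rtol=1e-12)

    def test_adjusted_values_monotone_in_raw_p(self, rng):
        p = np.sort(rng.uniform(size=25))
        from statsmodels.stats.multitest import multipletests

        _, fdr, _, _ = multipletests(p, method="fdr_bh")
        assert (np.diff(fdr) >= -1e-15).all()
        assert ((fdr >= 0) & (fdr <= 1)).all()
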