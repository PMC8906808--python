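"""Droplet QC filters and the cluster marker-gene test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from somitoscreen import (
    compute_cell_qc,
    filter_cells,
    generate_count_matrix,
    marker_genes,
    normalize_cp10k,
    wilcoxon_rank_sum,
)


def matrix_from_cells(cells: dict[str, dict[str, int]], genes: list[str]):
    """Build a genes × cells frame from per-cell sparse count dicts."""
    df = pd.DataFrame(0, index=genes, columns=list(cells), dtype=np.int64)
    for cell, counts in cells.items():
        for gene, n in counts.items():
            df.loc[gene, cell] = n
    return df


def spread_counts(total: int, genes: list[str]) -> dict[str, int]:
    """Distribute ``total`` UMIs over all listed genes, one-ish each."""
    base = total // len(genes)
    rem = total - base * len(genes)
    out = {g: base for g in genes}
    for g in genes[:rem]:
        out[g] += 1
    return {g: n for g, n in out.items() if n > 0}


class TestComputeCellQC:
    GENES = [f"G{i}" for i in range(1200)] + ["MT-1", "MT-2"]

    def test_complexity_boundary_cell_is_retained(self):
        """1000 genes at 5623 UMIs puts complexity at ~0.800007, just on
        the passing side of the strict less-than-0.8 exclusion."""
        cells = {"edge": spread_counts(5623, [f"G{i}" for i in range(1000)])}
        qc = compute_cell_qc(matrix_from_cells(cells, self.GENES))
        row = qc.loc["edge"]
        assert row["gene_count"] == 1000
        assert row["umi_count"] == 5623
        assert row["complexity"] >= 0.8
        assert not row["low_complexity"]
        assert row["pass"]

    def test_equal_genes_and_umis_give_complexity_one(self):
        cells = {"c": {f"G{i}": 1 for i in range(1000)}}
        qc = compute_cell_qc(matrix_from_cells(cells, self.GENES))
        assert qc.loc["c", "complexity"] == pytest.approx(1.0)
        assert qc.loc["c", "pass"]

    def test_exact_cutoff_cells_are_retained(self):
        """Exclusions are strict inequalities: 500 UMIs, 200 genes and
        mito fraction exactly 0.2 all pass."""
        counts = spread_counts(400, [f"G{i}" for i in range(200)])
        counts["MT-1"] = 100  # 100/500 = 0.2 exactly
        qc = compute_cell_qc(matrix_from_cells({"b": counts}, self.GENES))
        row = qc.loc["b"]
        assert row["umi_count"] == 500 and row["gene_count"] == 201
        assert row["mito_fraction"] == pytest.approx(0.2)
        assert not row[["low_umi", "low_genes", "high_mito"]].any()

    def test_single_gene_cell_has_gene_count_one(self):
        qc = compute_cell_qc(matrix_from_cells({"c": {"G0": 900}}, self.GENES))
        assert qc.loc["c", "gene_count"] == 1
        assert qc.loc["c", "low_genes"]

    def test_umi_at_most_one_fails_complexity(self):
        qc = compute_cell_qc(matrix_from_cells({"c": {"G0": 1}}, self.GENES))
        assert np.isnan(qc.loc["c", "complexity"])
        assert qc.loc["c", "low_complexity"]
        assert not qc.loc["c", "pass"]

    def test_planted_matrix_failures_match_truth_exactly(self):
        res = generate_count_matrix(seed=13)
        qc = compute_cell_qc(res.counts)
        failing = set(qc.index[~qc["pass"]])
        planted_bad = set(res.truth.index[res.truth.planted_class != "good"])
        assert failing == planted_bad

    def test_negative_and_fractional_counts_rejected(self):
        bad = pd.DataFrame([[1, -1]], index=["G0"], columns=["a", "b"])
        with pytest.raises(ValueError):
            compute_cell_qc(bad)
        frac = pd.DataFrame([[0.5, 1.0]], index=["G0"], columns=["a", "b"])
        with pytest.raises(ValueError):
            compute_cell_qc(frac)

    def test_mito_monotonicity_never_rescues_a_cell(self):
        """Raising mitochondrial fraction (UMIs fixed) can only flip
        pass → fail, never fail → pass."""
        genes = [f"G{i}" for i in range(400)] + ["MT-1"]
        statuses = []
        for mito_umis in (0, 100, 200, 300, 400):
            counts = spread_counts(2000 - mito_umis, genes[:300])
            if mito_umis:
                counts["MT-1"] = mito_umis
            qc = compute_cell_qc(matrix_from_cells({"c": counts}, genes))
            statuses.append(bool(qc.loc["c", "pass"]))
        # once failed, stays failed as mito rises
        first_fail = statuses.index(False) if False in statuses else len(statuses)
        assert all(not s for s in statuses[first_fail:])


class TestFilterCells:
    def test_all_pass_keeps_matrix_unchanged(self):
        genes = [f"G{i}" for i in range(900)] + ["MT-1"]
        cells = {f"c{i}": spread_counts(2000, genes[:800]) for i in range(4)}
        counts = matrix_from_cells(cells, genes)
        qc = compute_cell_qc(counts)
        filtered, report = filter_cells(qc, counts)
        pd.testing.assert_frame_equal(filtered, counts)
        assert report["n_removed"] == 0

    def test_all_cells_bad_is_an_error(self):
        genes = [f"G{i}" for i in range(300)]
        cells = {f"c{i}": {"G0": 50} for i in range(3)}  # low UMI, low genes
        counts = matrix_from_cells(cells, genes)
        qc = compute_cell_qc(counts)
        with pytest.raises(ValueError, match="no cells pass"):
            filter_cells(qc, counts)

    def test_mixed_matrix_retains_exactly_the_good_cells(self):
        res = generate_count_matrix(seed=17)
        qc = compute_cell_qc(res.counts)
        filtered, report = filter_cells(qc, res.counts)
        n_good = int((res.truth.planted_class == "good").sum())
        assert report["n_retained"] == n_good
        assert set(filtered.columns) == set(
            res.truth.index[res.truth.planted_class == "good"]
        )
        assert report["n_input"] - report["n_retained"] == report["n_removed"]


class TestWilcoxonRankSum:
    def test_completely_separated_groups_of_four(self):
        assert wilcoxon_rank_sum([1, 2, 3, 4], [5, 6, 7, 8]) == pytest.approx(
            2.0 / 70.0
        )

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_exact_branch_matches_scipy_enumeration(self, data):
        n = data.draw(st.integers(2, 8))
        m = data.draw(st.integers(2, 8))
        # tie-free values so scipy's exact method is a valid oracle
        pool = data.draw(
            st.lists(
                st.floats(-100, 100, allow_nan=False),
                min_size=n + m,
                max_size=n + m,
                unique=True,
            )
        )
        x, y = pool[:n], pool[n:]
        ours = wilcoxon_rank_sum(x, y)
        oracle = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours == pytest.approx(oracle.pvalue, rel=1e-9)

    def test_exact_branch_handles_ties(self):
        # permutation oracle by hand: pooled [1,1,2] split 1 vs 2
        # rank sums for the singleton: {1.5, 1.5, 3}; observed x=[2] → 3
        # |W−µ|=1 ; hits: only W=3 → p = 1/3
        assert wilcoxon_rank_sum([2], [1, 1]) == pytest.approx(1.0 / 3.0)

    def test_large_sample_branch_close_to_scipy_asymptotics(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 1.0, 30)
        y = rng.normal(0.8, 1.0, 40)
        ours = wilcoxon_rank_sum(x, y)
        oracle = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert ours == pytest.approx(oracle.pvalue, rel=1e-9)


class TestMarkerGenes:
    def make_normalized(self, seed=0):
        res = generate_count_matrix(seed=seed)
        good = (res.truth.planted_class == "good").to_numpy()
        counts = res.counts.loc[:, good]
        labels = res.truth.cluster[good]
        return normalize_cp10k(counts), labels, res

    def test_identical_gene_is_never_a_marker(self):
        rng = np.random.default_rng(1)
        normalized = pd.DataFrame(
            np.log1p(rng.uniform(0, 5, size=(30, 40))),
            index=[f"G{i}" for i in range(30)],
            columns=[f"c{i}" for i in range(40)],
        )
        normalized.iloc[0] = 1.3  # identical in and out of every cluster
        labels = ["a"] * 20 + ["b"] * 20
        out = marker_genes(normalized, labels)
        g0 = out[out.gene == "G0"]
        assert (g0.log2_fold_change == 0).all()
        assert not g0.is_marker.any()

    def test_planted_markers_found_with_high_specificity(self):
        normalized, labels, res = self.make_normalized(seed=19)
        out = marker_genes(normalized, labels)
        all_markers = set(sum(res.cluster_markers.values(), []))
        for cluster, genes in res.cluster_markers.items():
            sub = out[out.cluster == cluster].set_index("gene")
            assert sub.loc[genes, "is_marker"].all()
            null = sub.drop(index=[g for g in all_markers if g in sub.index])
            assert (~null.is_marker).mean() >= 0.95

    def test_bonferroni_and_marker_rule_consistency(self):
        normalized, labels, _ = self.make_normalized(seed=23)
        out = marker_genes(normalized, labels)
        n_tested = out.groupby("cluster")["gene"].transform("size")
        expected = np.minimum(1.0, out.p_value * n_tested)
        assert np.allclose(out.p_adjusted, expected)
        rule = (out.log2_fold_change >= 0.25) & (out.p_adjusted < 0.05)
        assert (out.is_marker == rule).all()

    def test_permuted_labels_yield_no_markers(self):
        """Bonferroni keeps the family-wise error rate ≤ 5%: permuted
        cluster labels should essentially never produce a marker."""
        normalized, labels, _ = self.make_normalized(seed=29)
        rng = np.random.default_rng(0)
        with_markers = 0
        for _ in range(5):
            permuted = rng.permutation(np.asarray(labels))
            out = marker_genes(normalized, permuted)
            with_markers += bool(out.is_marker.any())
        assert with_markers <= 1

    def test_single_cluster_rejected_and_tiny_cluster_skipped(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(
            rng.integers(0, 30, size=(20, 10)),
            index=[f"G{i}" for i in range(20)],
            columns=[f"c{i}" for i in range(10)],
        )
        norm = normalize_cp10k(data)
        with pytest.raises(ValueError):
            marker_genes(norm, ["a"] * 10)
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = marker_genes(norm, ["a"] * 9 + ["b"])
        assert set(out.cluster) == {"a"}
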