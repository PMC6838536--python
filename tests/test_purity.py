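"""Cell filtering, clustering contract, identity assignment and purity."""

import numpy as np
import pandas as pd
import pytest

from crosstalker import (
    ClusterAssignment,
    SingleCellMatrix,
    assign_cluster_identity,
    cluster_cells,
    compute_purity,
    filter_cells,
    generate_single_cell,
    genes_per_cell,
    top_enriched_genes,
)


class TestFilterCells:
    def test_strict_inequality_at_boundary(self, toy_matrix):
        # totals 1500, 1501, 3000, 0, 6, 40: "more than 1,500" keeps two
        retained = filter_cells(toy_matrix, 1500)
        assert retained.cell_ids == ["c2", "c3"]

    def test_threshold_zero_keeps_cells_with_any_transcript(self, toy_matrix):
        retained = filter_cells(toy_matrix, 0)
        assert "c4" not in retained.cell_ids and retained.n_cells == 5

    def test_idempotent_and_monotone(self, toy_matrix):
        once = filter_cells(toy_matrix, 30)
        twice = filter_cells(once, 30)
        assert once.cell_ids == twice.cell_ids
        previous = toy_matrix.n_cells + 1
        for t in (0, 6, 40, 1500, 1501, 3000):
            n = filter_cells(toy_matrix, t).n_cells
            assert n <= previous
            previous = n

    def test_matches_brute_force_recount_on_synthetic(self):
        matrix, _ = generate_single_cell(cells_per_gate=40, seed=3)
        retained = set(filter_cells(matrix, 1500).cell_ids)
        expected = {c for c in matrix.cell_ids if matrix.counts[c].sum() > 1500}
        assert retained == expected

    def test_removing_every_cell_warns(self, toy_matrix, caplog):
        with caplog.at_level("WARNING", logger="crosstalker"):
            empty = filter_cells(toy_matrix, 10**9)
        assert empty.n_cells == 0
        assert any("every cell" in r.message for r in caplog.records)


class TestGenesPerCell:
    def test_counts_nonzero_genes(self):
        counts = pd.DataFrame(
            {"c1": [0, 3, 0, 1], "c2": [0, 0, 0, 0]}, index=[f"g{i}" for i in range(4)]
        )
        matrix = SingleCellMatrix(counts=counts, gate_labels=pd.Series({"c1": "a", "c2": "a"}))
        per_cell, mean, _ = genes_per_cell(matrix)
        assert per_cell["c1"] == 2 and per_cell["c2"] == 0
        assert mean == 1.0

    def test_matches_brute_force_on_synthetic(self):
        matrix, _ = generate_single_cell(cells_per_gate=20, seed=4)
        per_cell, mean, sem = genes_per_cell(matrix)
        expected = {
            c: sum(1 for v in matrix.counts[c] if v > 0) for c in matrix.cell_ids
        }
        assert per_cell.to_dict() == expected
        values = list(expected.values())
        assert mean == pytest.approx(np.mean(values))
        assert sem == pytest.approx(np.std(values, ddof=1) / np.sqrt(len(values)))


class TestClustering:
    def test_two_separable_types_recovered_exactly(self):
        matrix, truth = generate_single_cell(
            n_types=2, cells_per_gate=40, contamination=0.0, seed=5, nb_dispersion=10.0
        )
        assignment = cluster_cells(matrix, k=2, seed=0)
        frame = pd.DataFrame(
            {
                "cluster": assignment.labels,
                "truth": [truth.cell_true_types[c] for c in assignment.labels.index],
            }
        )
        # identical partition up to label permutation
        assert (frame.groupby("cluster")["truth"].nunique() == 1).all()
        assert frame.groupby("truth")["cluster"].nunique().eq(1).all()

    def test_k_one_is_a_single_cluster(self):
        matrix, _ = generate_single_cell(n_types=2, cells_per_gate=10, seed=6)
        assignment = cluster_cells(matrix, k=1, seed=0)
        assert assignment.n_clusters == 1 and len(assignment.labels) == matrix.n_cells

    def test_k_exceeding_cells_rejected(self):
        matrix, _ = generate_single_cell(n_types=2, cells_per_gate=3, seed=7)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_cells(matrix, k=10, seed=0)

    def test_deterministic_under_seed(self):
        matrix, _ = generate_single_cell(cells_per_gate=30, contamination=0.05, seed=8)
        a = cluster_cells(matrix, k=4, seed=1)
        b = cluster_cells(matrix, k=4, seed=1)
        pd.testing.assert_series_equal(a.labels, b.labels)

    def test_four_types_high_agreement_across_seeds(self):
        from sklearn.metrics import adjusted_rand_score

        for seed in range(5):
            matrix, truth = generate_single_cell(
                cells_per_gate=60, contamination=0.0, seed=seed
            )
            assignment = cluster_cells(matrix, k=4, seed=seed)
            truth_labels = [truth.cell_true_types[c] for c in assignment.labels.index]
            assert adjusted_rand_score(truth_labels, assignment.labels) >= 0.95


class TestIdentityAssignment:
    def test_cluster_expressing_one_panel_gets_that_type(self):
        counts = pd.DataFrame(
            {"c1": [9, 0], "c2": [8, 0], "c3": [0, 7], "c4": [0, 9]},
            index=["markerA", "markerB"],
        )
        matrix = SingleCellMatrix(
            counts=counts, gate_labels=pd.Series({c: "g" for c in counts.columns})
        )
        assignment = ClusterAssignment(
            labels=pd.Series([0, 0, 1, 1], index=counts.columns)
        )
        identity, scores = assign_cluster_identity(
            matrix, assignment, {"typeA": ["markerA"], "typeB": ["markerB"]}
        )
        assert identity == {0: "typeA", 1: "typeB"}
        assert scores.shape == (2, 2)

    def test_tie_breaks_lexicographically_with_warning(self, caplog):
        counts = pd.DataFrame({"c1": [5, 5], "c2": [5, 5]}, index=["m1", "m2"])
        matrix = SingleCellMatrix(
            counts=counts, gate_labels=pd.Series({"c1": "g", "c2": "g"})
        )
        assignment = ClusterAssignment(labels=pd.Series([0, 0], index=["c1", "c2"]))
        with caplog.at_level("WARNING", logger="crosstalker"):
            identity, _ = assign_cluster_identity(
                matrix, assignment, {"zeta": ["m1"], "alpha": ["m2"]}
            )
        assert identity == {0: "alpha"}
        assert any("tie-break" in r.message for r in caplog.records)

    def test_missing_panel_genes_warned_and_skipped(self, caplog):
        matrix, truth = generate_single_cell(cells_per_gate=20, seed=9)
        assignment = cluster_cells(matrix, k=4, seed=0)
        panels = {t: list(g) + ["NotAGene"] for t, g in truth.marker_genes.items()}
        with caplog.at_level("WARNING", logger="crosstalker"):
            identity, _ = assign_cluster_identity(matrix, assignment, panels)
        assert any("absent" in r.message for r in caplog.records)
        assert set(identity.values()) <= set(truth.marker_genes)

    def test_synthetic_mapping_matches_planted_identities(self):
        matrix, truth = generate_single_cell(cells_per_gate=50, contamination=0.0, seed=10)
        assignment = cluster_cells(matrix, k=4, seed=0)
        identity, _ = assign_cluster_identity(
            matrix, assignment, {t: list(g) for t, g in truth.marker_genes.items()}
        )
        for cluster, cell_type in identity.items():
            members = assignment.cells_in(cluster)
            true_types = {truth.cell_true_types[c] for c in members}
            assert true_types == {cell_type}


class TestPurity:
    def _report(self, inferred_per_cell: dict[str, str], gates: dict[str, str], expected):
        # one singleton cluster per cell makes the inferred identity explicit
        cells = list(inferred_per_cell)
        assignment = ClusterAssignment(
            labels=pd.Series(range(len(cells)), index=cells)
        )
        identity_map = {i: inferred_per_cell[c] for i, c in enumerate(cells)}
        return compute_purity(assignment, identity_map, pd.Series(gates), expected)

    def test_96_of_100_is_96_percent(self):
        inferred = {f"c{i}": ("neural" if i < 96 else "mural") for i in range(100)}
        gates = {c: "neural_gate" for c in inferred}
        report = self._report(inferred, gates, {"neural_gate": "neural"})
        assert report.purity["neural_gate"] == 96.0
        assert report.n_cells["neural_gate"] == 100
        assert report.confusion.loc["neural_gate"].sum() == 100

    def test_empty_gate_is_missing_not_zero_or_hundred(self):
        inferred = {"c1": "neural"}
        gates = {"c1": "gA"}
        report = self._report(inferred, gates, {"gA": "neural", "gB": "neural"})
        assert np.isnan(report.purity["gB"]) and report.n_cells["gB"] == 0

    def test_invariant_under_cluster_relabeling(self):
        matrix, truth = generate_single_cell(cells_per_gate=30, contamination=0.1, seed=11)
        assignment = cluster_cells(matrix, k=4, seed=0)
        panels = {t: list(g) for t, g in truth.marker_genes.items()}
        identity, _ = assign_cluster_identity(matrix, assignment, panels)
        report = compute_purity(
            assignment, identity, matrix.gate_labels, truth.expected_type_per_gate
        )
        permuted = ClusterAssignment(labels=(assignment.labels + 7) % 1000)
        identity_perm = {(c + 7) % 1000: t for c, t in identity.items()}
        report_perm = compute_purity(
            permuted, identity_perm, matrix.gate_labels, truth.expected_type_per_gate
        )
        assert report.purity == report_perm.purity

    def test_zero_contamination_is_exactly_100(self):
        matrix, truth = generate_single_cell(cells_per_gate=40, contamination=0.0, seed=12)
        filtered = filter_cells(matrix, 1500)
        assignment = cluster_cells(filtered, k=4, seed=0)
        identity, _ = assign_cluster_identity(
            filtered, assignment, {t: list(g) for t, g in truth.marker_genes.items()}
        )
        report = compute_purity(
            assignment, identity, filtered.gate_labels, truth.expected_type_per_gate
        )
        assert all(v == 100.0 for v in report.purity.values())


class TestTopEnrichedGenes:
    def _matrix(self, cluster_means: dict[str, list[float]], cells_per_cluster=3):
        genes = list(cluster_means)
        n_clusters = len(next(iter(cluster_means.values())))
        cols, labels = {}, {}
        for c in range(n_clusters):
            for i in range(cells_per_cluster):
                cell = f"k{c}_{i}"
                cols[cell] = [cluster_means[g][c] for g in genes]
                labels[cell] = c
        counts = pd.DataFrame(cols, index=genes)
        matrix = SingleCellMatrix(
            counts=counts.astype(int), gate_labels=pd.Series({c: "g" for c in cols})
        )
        assignment = ClusterAssignment(labels=pd.Series(labels))
        return matrix, assignment

    def test_analytic_enrichment_example(self):
        # balance gene keeps every cell at equal depth, so normalisation is
        # neutral and scores are exact
        matrix, assignment = self._matrix(
            {"spec": [40, 0, 0, 0], "flat": [40, 40, 40, 40], "bal": [0, 40, 40, 40]}
        )
        result = top_enriched_genes(matrix, assignment, n=2)
        assert result[0].loc["spec", "enrichment"] == pytest.approx(4.0)
        assert result[0].loc["flat", "enrichment"] == pytest.approx(1.0)
        assert list(result[0].index) == ["spec", "flat"]  # specific outranks uniform

    def test_uniform_gene_scores_one_everywhere(self):
        matrix, assignment = self._matrix(
            {"flat": [30, 30, 30], "spec": [30, 0, 0], "bal": [0, 30, 30]}
        )
        result = top_enriched_genes(matrix, assignment, n=3)
        for c in result:
            assert result[c].loc["flat", "enrichment"] == pytest.approx(1.0)

    def test_mean_enrichment_across_clusters_is_one(self):
        matrix, truth = generate_single_cell(cells_per_gate=30, seed=13)
        assignment = cluster_cells(matrix, k=4, seed=0)
        from crosstalker.purity import normalize_counts

        norm = normalize_counts(matrix)
        cluster_means = pd.DataFrame(
            {c: norm.loc[:, assignment.cells_in(c)].mean(axis=1) for c in range(4)}
        )
        overall = cluster_means.mean(axis=1)
        enr = cluster_means.loc[overall > 0].div(overall[overall > 0], axis=0)
        assert np.allclose(enr.mean(axis=1), 1.0, atol=1e-9)

    def test_planted_markers_dominate_their_cluster(self):
        matrix, truth = generate_single_cell(
            cells_per_gate=50, contamination=0.0, seed=14, nb_dispersion=10.0
        )
        assignment = cluster_cells(matrix, k=4, seed=0)
        identity, _ = assign_cluster_identity(
            matrix, assignment, {t: list(g) for t, g in truth.marker_genes.items()}
        )
        result = top_enriched_genes(matrix, assignment, n=10)
        for cluster, cell_type in identity.items():
            top = set(result[cluster].index)
            overlap = top & set(truth.marker_genes[cell_type])
            assert len(overlap) >= 8  # top-10 drawn from the planted 10-gene panel

    def test_n_beyond_gene_count_returns_all_with_warning(self, caplog):
        matrix, assignment = self._matrix({"a": [5, 1], "b": [1, 5]})
        with caplog.at_level("WARNING", logger="crosstalker"):
            result = top_enriched_genes(matrix, assignment, n=99)
        assert len(result[0]) == 2
        assert any("returning all" in r.message for r in caplog.records)

    def test_fewer_than_two_clusters_rejected(self):
        matrix, assignment = self._matrix({"a": [5], "b": [1]})
        from crosstalker import ValidationError

        with pytest.raises(ValidationError):
            top_enriched_genes(matrix, assignment, n=2)
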