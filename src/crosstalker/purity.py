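"""FACS-gate purity quantification from single-cell transcriptomes.

Implements the computational validation arm for sorted populations: cells
are kept when they carry strictly more than a minimum number of transcripts
(1,500 by default), clustered without supervision, each cluster is assigned
a cell-type identity from marker panels, and every gate's purity is the
percentage of its cells whose cluster identity matches the type the gate
was designed to capture. Per-cluster enriched genes (expression relative to
the mean across clusters) document what each cluster is.

The clustering stage is a contract, not a fixed algorithm: any function
mapping a filtered matrix to a cell -> cluster assignment can stand in.
The default is k-means on depth-normalised log1p counts over the most
variable genes, which suffices for the well-separated populations this
validation concerns; purity itself is agnostic to the clusterer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io_formats import SingleCellMatrix, ValidationError

logger = logging.getLogger("crosstalker")


@dataclass(frozen=True)
class ClusterAssignment:
    """Cell -> integer cluster labels covering every retained cell."""

    labels: pd.Series  # indexed by cell id, integer cluster ids

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels))

    def cells_in(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


@dataclass(frozen=True)
class PurityReport:
    """Gate x inferred-identity confusion counts and per-gate purity (%).

    ``purity`` maps each gate to the percentage of its cells whose inferred
    identity matches the expected type; a gate with zero cells is reported
    as missing (NaN), never as 0 or 100.
    """

    confusion: pd.DataFrame  # gates x identities, counts
    purity: dict[str, float]
    n_cells: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        frame = self.confusion.copy()
        frame["n_cells"] = pd.Series(self.n_cells)
        frame["purity_percent"] = pd.Series(self.purity)
        return frame


# ---------------------------------------------------------------------------
# Cell-level filters and statistics
# ---------------------------------------------------------------------------


def filter_cells(matrix: SingleCellMatrix, min_transcripts: int = 1500) -> SingleCellMatrix:
    """Keep cells with strictly more than ``min_transcripts`` total transcripts.

    A cell at exactly the threshold is removed ("more than", not "at
    least"). Retained/removed counts are logged; removing every cell is a
    warning, not a silent empty success.
    """
    if min_transcripts < 0:
        raise ValueError("min_transcripts must be >= 0")
    totals = matrix.counts.sum(axis=0)
    keep = totals > min_transcripts
    retained = matrix.counts.loc[:, keep]
    logger.info(
        "transcript filter (> %d): retained %d / %d cells",
        min_transcripts, int(keep.sum()), matrix.n_cells,
    )
    if retained.shape[1] == 0:
        logger.warning("transcript filter removed every cell")
    return SingleCellMatrix(counts=retained, gate_labels=matrix.gate_labels)


def genes_per_cell(matrix: SingleCellMatrix) -> tuple[pd.Series, float, float]:
    """Number of distinct genes detected (count > 0) per cell.

    Returns the per-cell series plus its mean and standard error.
    """
    per_cell = (matrix.counts > 0).sum(axis=0).astype(int)
    per_cell.name = "genes_detected"
    mean = float(per_cell.mean()) if len(per_cell) else float("nan")
    sem = (
        float(per_cell.std(ddof=1) / np.sqrt(len(per_cell)))
        if len(per_cell) > 1
        else float("nan")
    )
    return per_cell, mean, sem


# ---------------------------------------------------------------------------
# Clustering and identity assignment
# ---------------------------------------------------------------------------


def normalize_counts(matrix: SingleCellMatrix) -> pd.DataFrame:
    """Scale every cell to the median total count (depth normalisation)."""
    totals = matrix.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValidationError("cannot normalise cells with zero total count")
    target = float(totals.median())
    return matrix.counts.astype(float) * (target / totals)


def cluster_cells(
    matrix: SingleCellMatrix,
    k: int | str = 4,
    seed: int = 0,
    n_top_genes: int = 500,
) -> ClusterAssignment:
    """Unsupervised clustering of cells (default: k-means).

    Cells are depth-normalised, log1p-transformed, restricted to the
    ``n_top_genes`` most variable genes, then k-means partitioned.
    ``k="auto"`` scans 2..10 and keeps the best mean silhouette. The result
    is deterministic for a fixed seed.
    """
    n_cells = matrix.n_cells
    if n_cells == 0:
        raise ValidationError("cannot cluster an empty matrix")
    log_norm = np.log1p(normalize_counts(matrix))
    variances = log_norm.var(axis=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top_genes]
    features = log_norm.loc[top].to_numpy().T  # cells x genes

    if k == "auto":
        best_k, best_score = 2, -np.inf
        for candidate in range(2, min(10, n_cells - 1) + 1):
            labels = KMeans(n_clusters=candidate, random_state=seed, n_init=10).fit_predict(features)
            score = silhouette_score(features, labels)
            if score > best_score:
                best_k, best_score = candidate, score
        k = best_k
        logger.info("auto-selected k=%d (silhouette %.3f)", best_k, best_score)
    if not isinstance(k, int) or k < 1:
        raise ValueError(f"k must be a positive integer or 'auto', got {k!r}")
    if k > n_cells:
        raise ValueError(f"k={k} exceeds the {n_cells} available cells")
    if k == 1:
        labels = np.zeros(n_cells, dtype=int)
    else:
        labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(features)
    return ClusterAssignment(
        labels=pd.Series(labels.astype(int), index=matrix.cell_ids, name="cluster")
    )


def assign_cluster_identity(
    matrix: SingleCellMatrix,
    assignment: ClusterAssignment,
    marker_panels: dict[str, list[str] | tuple[str, ...]],
) -> tuple[dict[int, str], pd.DataFrame]:
    """Assign each cluster the type whose marker panel it expresses most.

    The score of panel P in cluster c is the mean depth-normalised
    expression of P's genes over c's cells; each cluster takes the
    arg-max type. Panel genes missing from the matrix are warned about and
    skipped. Ties (including all-zero clusters) break lexicographically on
    type name with a warning. Returns the mapping plus the full score
    table for audit.
    """
    norm = normalize_counts(matrix)
    panels = {}
    for cell_type, genes in marker_panels.items():
        present = [g for g in genes if g in norm.index]
        missing = set(genes) - set(present)
        if missing:
            logger.warning(
                "panel %r: %d marker genes absent from matrix, skipped",
                cell_type, len(missing),
            )
        if not present:
            raise ValidationError(f"no panel gene of type {cell_type!r} is in the matrix")
        panels[cell_type] = present

    clusters = sorted(set(assignment.labels))
    scores = pd.DataFrame(index=clusters, columns=sorted(panels), dtype=float)
    for cluster in clusters:
        cells = assignment.cells_in(cluster)
        for cell_type in scores.columns:
            scores.at[cluster, cell_type] = float(
                norm.loc[panels[cell_type], cells].to_numpy().mean()
            )
    identity: dict[int, str] = {}
    for cluster in clusters:
        row = scores.loc[cluster]
        best = row.max()
        winners = sorted(row.index[row >= best])
        if len(winners) > 1 or best == 0:
            logger.warning(
                "cluster %d: ambiguous identity (score %.3g for %s), "
                "lexicographic tie-break, low confidence",
                cluster, best, winners,
            )
        identity[cluster] = winners[0]
    scores.index.name = "cluster"
    return identity, scores


# ---------------------------------------------------------------------------
# Purity and per-cluster enrichment
# ---------------------------------------------------------------------------


def compute_purity(
    assignment: ClusterAssignment,
    identity_map: dict[int, str],
    gate_labels: pd.Series,
    expected_type_per_gate: dict[str, str],
) -> PurityReport:
    """Fraction (as %) of each gate's cells whose inferred identity matches.

    A cell's inferred identity is the type of its cluster. Purity of gate g
    is ``100 * matching / total`` over g's retained cells; the confusion
    table holds the full gate x identity counts (rows sum to the gate's
    cell count).
    """
    cells = list(assignment.labels.index)
    missing = [c for c in cells if c not in gate_labels.index]
    if missing:
        raise ValidationError(f"{len(missing)} clustered cells have no gate label")
    inferred = assignment.labels.map(identity_map)
    gates = sorted(expected_type_per_gate)
    identities = sorted(set(identity_map.values()) | set(expected_type_per_gate.values()))
    confusion = pd.DataFrame(0, index=gates, columns=identities, dtype=int)
    for cell in cells:
        gate = gate_labels[cell]
        if gate in confusion.index:
            confusion.at[gate, inferred[cell]] += 1
    purity: dict[str, float] = {}
    n_cells: dict[str, int] = {}
    for gate in gates:
        total = int(confusion.loc[gate].sum())
        n_cells[gate] = total
        if total == 0:
            purity[gate] = float("nan")
            logger.warning("gate %r has no retained cells; purity undefined", gate)
        else:
            purity[gate] = float(
                100.0 * confusion.at[gate, expected_type_per_gate[gate]] / total
            )
    confusion.index.name = "gate"
    confusion.columns.name = "identity"
    return PurityReport(confusion=confusion, purity=purity, n_cells=n_cells)


def top_enriched_genes(
    matrix: SingleCellMatrix,
    assignment: ClusterAssignment,
    n: int = 10,
) -> dict[int, pd.DataFrame]:
    """Per-cluster top-n genes by expression relative to the cluster mean.

    A gene's enrichment in cluster c is its mean depth-normalised
    expression in c divided by the mean of those per-cluster means, so a
    uniformly expressed gene scores 1 everywhere and can never outrank a
    cluster-specific one. Genes never detected are excluded. Ties break by
    higher absolute expression, then gene symbol.
    """
    clusters = sorted(set(assignment.labels))
    if len(clusters) < 2:
        raise ValidationError("per-cluster enrichment needs >= 2 clusters")
    norm = normalize_counts(matrix)
    cluster_means = pd.DataFrame(
        {c: norm.loc[:, assignment.cells_in(c)].mean(axis=1) for c in clusters}
    )
    overall = cluster_means.mean(axis=1)
    nonzero = overall > 0
    cluster_means = cluster_means.loc[nonzero]
    enrichment = cluster_means.div(overall.loc[nonzero], axis=0)
    if n > enrichment.shape[0]:
        logger.warning(
            "requested top %d genes but only %d available; returning all",
            n, enrichment.shape[0],
        )
    result: dict[int, pd.DataFrame] = {}
    for c in clusters:
        frame = pd.DataFrame(
            {
                "enrichment": enrichment[c],
                "mean_expression": cluster_means[c],
            }
        )
        frame = (
            frame.reset_index(names="gene")
            .sort_values(
                by=["enrichment", "mean_expression", "gene"],
                ascending=[False, False, True],
                kind="stable",
            )
            .set_index("gene")
        )
        result[c] = frame.head(n)
    return result
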