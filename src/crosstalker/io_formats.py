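"""Readers, writers and validated containers for every external format.

All tabular formats are tab-separated UTF-8 with a header row and decimal
points; sparse count matrices use MatrixMarket integer triplets with
sidecar gene/cell name files; networks round-trip through an edge-list TSV
or an explorer-oriented JSON document.

Containers validate on construction and reject (never coerce) negative,
non-finite or duplicated entries, so downstream stages can assume clean
inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("crosstalker")

#: Column names of the Ramilowski et al. ligand-receptor catalogue dialect.
DEFAULT_LIGAND_COL = "Ligand.ApprovedSymbol"
DEFAULT_RECEPTOR_COL = "Receptor.ApprovedSymbol"


class FormatError(ValueError):
    """A stream does not parse as the expected tabular/JSON dialect."""


class ValidationError(ValueError):
    """Parsed data violates a container invariant (negative FPKM, ...)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionProfile:
    """Genes x cell-population matrix of non-negative expression (FPKM).

    ``data`` is indexed by gene symbol (unique, case preserved) with one
    column per population; column order is meaningful and preserved.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValidationError(
                f"expression profile needs >= 2 populations, got {self.data.shape[1]}"
            )
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dups[:5]}")
        if self.data.columns.duplicated().any():
            raise ValidationError("duplicate population names")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("expression values must be finite (no NaN/inf)")
        if (values < 0).any():
            bad = self.data[(self.data < 0).any(axis=1)].index[0]
            raise ValidationError(f"negative expression value for gene {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def type_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_types(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class LRDatabase:
    """Catalogue of (ligand symbol, receptor symbol) gene pairs."""

    pairs: frozenset[tuple[str, str]]
    source_tag: str = ""

    def __post_init__(self) -> None:
        for lig, rec in self.pairs:
            if not lig or not rec:
                raise ValidationError("empty gene symbol in ligand-receptor pair")

    def __len__(self) -> int:
        return len(self.pairs)

    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)


@dataclass(frozen=True)
class SingleCellMatrix:
    """Genes x cells transcript counts with one FACS-gate label per cell."""

    counts: pd.DataFrame  # genes x cells, non-negative integers
    gate_labels: pd.Series  # indexed by cell id -> gate name

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate cell ids in count matrix")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            as_float = values.astype(float)
            if not np.isfinite(as_float).all() or (as_float != np.round(as_float)).any():
                raise ValidationError("counts must be non-negative integers")
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.gate_labels.index)
        if missing:
            raise ValidationError(
                f"{len(missing)} cells lack a gate label (e.g. {sorted(missing)[:3]})"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gates(self) -> list[str]:
        return sorted(set(self.gate_labels.loc[list(self.counts.columns)]))


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------


def read_expression_table(
    source: str | Path | IO[str],
    fpkm_column_map: Mapping[str, str] | None = None,
    duplicate_policy: str = "strict",
) -> ExpressionProfile:
    """Read a genes x populations FPKM table from TSV.

    The first column holds gene symbols; remaining columns are numeric
    FPKM per population. ``fpkm_column_map`` optionally renames columns
    (original name -> population name). Duplicate gene symbols error under
    ``duplicate_policy="strict"`` (default) or are averaged under
    ``"collapse"``.
    """
    if duplicate_policy not in ("strict", "collapse"):
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
    try:
        table = pd.read_csv(source, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("empty expression table") from exc
    if table.shape[0] == 0 or table.shape[1] < 2:
        raise FormatError(
            f"expression table needs >= 1 gene row and >= 2 columns, got shape {table.shape}"
        )
    gene_col = table.columns[0]
    table = table.set_index(gene_col)
    if fpkm_column_map:
        table = table.rename(columns=dict(fpkm_column_map))
    numeric = pd.DataFrame(index=table.index)
    for col in table.columns:
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna()
        if bad.any():
            row = table.index[bad][0]
            raise FormatError(
                f"non-numeric expression value {table.loc[row, col]!r} "
                f"at gene {row!r}, column {col!r}"
            )
        if converted.isna().any():
            row = table.index[converted.isna()][0]
            raise FormatError(f"missing expression value at gene {row!r}, column {col!r}")
        numeric[col] = converted.astype(float)
    if numeric.index.duplicated().any():
        if duplicate_policy == "strict":
            dups = numeric.index[numeric.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"duplicate gene symbols under strict policy: {dups[:5]}"
            )
        logger.info(
            "collapsing %d duplicated gene symbols by averaging",
            int(numeric.index.duplicated().sum()),
        )
        numeric = numeric.groupby(level=0, sort=False).mean()
    numeric.index.name = None
    return ExpressionProfile(numeric)


def write_expression_table(profile: ExpressionProfile, dest: str | Path | IO[str]) -> None:
    """Write an expression profile as a TSV with a leading ``gene`` column."""
    profile.data.rename_axis("gene").to_csv(dest, sep="\t")


# ---------------------------------------------------------------------------
# Ligand-receptor pair tables
# ---------------------------------------------------------------------------


def read_lr_pairs(
    source: str | Path | IO[str],
    ligand_col: str = DEFAULT_LIGAND_COL,
    receptor_col: str = DEFAULT_RECEPTOR_COL,
    source_tag: str = "",
) -> LRDatabase:
    """Read a ligand-receptor pair catalogue from TSV.

    Defaults match the Ramilowski et al. supplementary dialect of two
    approved-gene-symbol columns. Rows de-duplicate as ordered
    (ligand, receptor) tuples.
    """
    try:
        table = pd.read_csv(source, sep="\t", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("empty ligand-receptor pair file") from exc
    for col in (ligand_col, receptor_col):
        if col not in table.columns:
            raise FormatError(
                f"column {col!r} not found; available columns: {list(table.columns)}"
            )
    if table.shape[0] == 0:
        raise FormatError("ligand-receptor pair file has a header but no rows")
    pairs = frozenset(
        (str(lig).strip(), str(rec).strip())
        for lig, rec in zip(table[ligand_col], table[receptor_col])
        if pd.notna(lig) and pd.notna(rec)
    )
    logger.info("read %d rows, retained %d unique ligand-receptor pairs", len(table), len(pairs))
    return LRDatabase(pairs=pairs, source_tag=source_tag)


def write_lr_pairs(
    db: LRDatabase,
    dest: str | Path | IO[str],
    ligand_col: str = DEFAULT_LIGAND_COL,
    receptor_col: str = DEFAULT_RECEPTOR_COL,
) -> None:
    frame = pd.DataFrame(db.sorted_pairs(), columns=[ligand_col, receptor_col])
    frame.to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Single-cell count matrices
# ---------------------------------------------------------------------------


def read_gate_labels(source: str | Path | IO[str]) -> pd.Series:
    """Read a two-column ``cell<TAB>gate`` TSV into a cell -> gate Series."""
    table = pd.read_csv(source, sep="\t", header=0, dtype=str)
    if table.shape[1] < 2:
        raise FormatError("gate label file needs columns: cell, gate")
    series = pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0].values, name="gate")
    if series.index.duplicated().any():
        raise ValidationError("duplicate cell ids in gate label file")
    return series


def read_count_matrix(
    source: str | Path | IO[str],
    gate_labels: str | Path | IO[str] | pd.Series,
    genes: str | Path | Sequence[str] | None = None,
    cells: str | Path | Sequence[str] | None = None,
    fmt: str = "dense",
    on_unlabelled: str = "error",
) -> SingleCellMatrix:
    """Read a genes x cells count matrix plus per-cell gate labels.

    ``fmt="dense"`` expects a TSV with gene symbols in the first column and
    one column per cell; ``fmt="mtx"`` expects a MatrixMarket triplet file
    plus ``genes``/``cells`` name lists (paths to one-name-per-line files or
    in-memory sequences). Cells without a gate label raise under
    ``on_unlabelled="error"`` or are dropped under ``"drop"``.
    """
    if fmt == "dense":
        table = pd.read_csv(source, sep="\t", header=0, index_col=0)
        counts = pd.DataFrame(
            table.to_numpy(), index=table.index.astype(str), columns=table.columns.astype(str)
        )
    elif fmt == "mtx":
        if genes is None or cells is None:
            raise ValueError("mtx format requires gene and cell name lists")
        matrix = scipy.io.mmread(source)
        if scipy.sparse.issparse(matrix):
            matrix = matrix.toarray()
        gene_names = _read_name_list(genes)
        cell_names = _read_name_list(cells)
        if matrix.shape != (len(gene_names), len(cell_names)):
            raise FormatError(
                f"matrix shape {matrix.shape} does not match "
                f"{len(gene_names)} genes x {len(cell_names)} cells"
            )
        counts = pd.DataFrame(matrix, index=gene_names, columns=cell_names)
    else:
        raise ValueError(f"unknown count matrix format {fmt!r}")
    values = counts.to_numpy().astype(float)
    if not np.isfinite(values).all() or (values < 0).any() or (values != np.round(values)).any():
        raise ValidationError("counts must be non-negative integers")
    counts = counts.astype(np.int64)
    counts.index.name = None
    counts.columns.name = None

    labels = gate_labels if isinstance(gate_labels, pd.Series) else read_gate_labels(gate_labels)
    unlabelled = [c for c in counts.columns if c not in labels.index]
    if unlabelled:
        if on_unlabelled == "drop":
            logger.warning("dropping %d unlabelled cells", len(unlabelled))
            counts = counts.drop(columns=unlabelled)
        else:
            raise ValidationError(
                f"{len(unlabelled)} of {counts.shape[1]} cells have no gate label "
                f"({len(labels)} labels provided)"
            )
    logger.info("count matrix: %d genes x %d labelled cells", *counts.shape)
    return SingleCellMatrix(counts=counts, gate_labels=labels)


def _read_name_list(source: str | Path | Sequence[str]) -> list[str]:
    if isinstance(source, (str, Path)):
        return [line.strip() for line in Path(source).read_text().splitlines() if line.strip()]
    return [str(name) for name in source]


def write_count_matrix_dense(matrix: SingleCellMatrix, dest: str | Path | IO[str]) -> None:
    matrix.counts.rename_axis("gene").to_csv(dest, sep="\t")


def write_count_matrix_mtx(
    matrix: SingleCellMatrix, mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> None:
    sparse = scipy.sparse.coo_matrix(matrix.counts.to_numpy())
    scipy.io.mmwrite(str(mtx_path), sparse, field="integer")
    Path(genes_path).write_text("\n".join(matrix.gene_ids) + "\n")
    Path(cells_path).write_text("\n".join(matrix.cell_ids) + "\n")


def write_gate_labels(matrix: SingleCellMatrix, dest: str | Path | IO[str]) -> None:
    frame = pd.DataFrame(
        {"cell": matrix.cell_ids, "gate": [matrix.gate_labels[c] for c in matrix.cell_ids]}
    )
    frame.to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Interaction networks (edge-list TSV and explorer JSON)
# ---------------------------------------------------------------------------

EDGE_COLUMNS = ["ligand", "receptor", "sender", "receiver", "strength"]


def write_network(network, dest: str | Path | IO[str], fmt: str = "tsv", enrichment=None) -> None:
    """Serialize a network as an edge-list TSV or an explorer JSON document.

    The JSON document carries population nodes, gene nodes with per-type
    enrichment vectors (when ``enrichment`` is given), directed edges and
    the thresholds the network was built with.
    """
    if fmt == "tsv":
        frame = pd.DataFrame(
            [(e.ligand, e.receptor, e.sender, e.receiver, e.strength) for e in network.edges],
            columns=EDGE_COLUMNS,
        )
        frame.to_csv(dest, sep="\t", index=False)
    elif fmt == "json":
        genes = sorted({e.ligand for e in network.edges} | {e.receptor for e in network.edges})
        gene_nodes = {}
        for gene in genes:
            node = {"symbol": gene}
            if enrichment is not None and gene in enrichment.scores.index:
                node["enrichment"] = {
                    t: float(v) for t, v in enrichment.scores.loc[gene].items()
                }
            gene_nodes[gene] = node
        document = {
            "populations": list(network.populations),
            "genes": gene_nodes,
            "edges": [
                {
                    "ligand": e.ligand,
                    "receptor": e.receptor,
                    "sender": e.sender,
                    "receiver": e.receiver,
                    "strength": e.strength,
                }
                for e in network.edges
            ],
            "metadata": dict(network.metadata),
        }
        if isinstance(dest, (str, Path)):
            Path(dest).write_text(json.dumps(document, indent=1))
        else:
            json.dump(document, dest, indent=1)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(source: str | Path | IO[str], populations: Iterable[str] | None = None):
    """Read an edge-list TSV back into an :class:`InteractionNetwork`."""
    from .interactome import EdgeRecord, InteractionNetwork

    frame = pd.read_csv(source, sep="\t", header=0)
    missing = [c for c in EDGE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"edge list missing columns {missing}")
    edges = [
        EdgeRecord(str(r.ligand), str(r.receptor), str(r.sender), str(r.receiver), float(r.strength))
        for r in frame.itertuples()
    ]
    if populations is None:
        populations = sorted({e.sender for e in edges} | {e.receiver for e in edges})
    return InteractionNetwork(edges=tuple(sorted(edges)), populations=tuple(populations))


def read_network_json(source: str | Path | IO[str]):
    from .interactome import EdgeRecord, InteractionNetwork

    if isinstance(source, (str, Path)):
        document = json.loads(Path(source).read_text())
    else:
        document = json.load(source)
    edges = tuple(
        sorted(
            EdgeRecord(e["ligand"], e["receptor"], e["sender"], e["receiver"], float(e["strength"]))
            for e in document["edges"]
        )
    )
    return InteractionNetwork(
        edges=edges,
        populations=tuple(document["populations"]),
        metadata=dict(document.get("metadata", {})),
    )
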