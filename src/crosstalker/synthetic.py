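"""Synthetic bulk and single-cell datasets with known planted structure.

The generators emulate the study design the pipeline targets: four sorted
brain populations (neural, mural, endothelial, microglial), each with a
panel of population-specific marker genes; ligand-receptor pairs planted
with high expression in designated sender/receiver populations and
near-zero expression elsewhere; background genes roughly uniform across
populations. Bulk FPKM values carry multiplicative lognormal noise
(expression is positive and right-skewed); single-cell transcript counts
are negative-binomial around type-specific mean profiles with lognormal
per-cell depth variation, and each FACS gate carries a controlled
contamination rate (cells whose true identity differs from the gate).

Every generated dataset returns a :class:`SyntheticTruth` recording the
planted markers, edges, identities and contamination, which downstream
parameter-recovery tests compare against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ExpressionProfile, LRDatabase, SingleCellMatrix

DEFAULT_TYPE_NAMES = ("neural", "mural", "endothelial", "microglia")

#: FPKM above which a gene counts as expressed in one population (the
#: pipeline's per-type call threshold; generators plant structure around it).
EXPRESSION_THRESHOLD = 10.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by a generator, for recovery tests.

    ``planted_edges`` are the directed (ligand, receptor, sender, receiver)
    tuples a perfect network reconstruction recovers; ``contamination`` maps
    each FACS gate to the fraction of its cells whose true identity is a
    different type; for single-cell data the per-cell gate and true identity
    are recorded too.
    """

    marker_genes: dict[str, tuple[str, ...]]
    planted_edges: frozenset[tuple[str, str, str, str]]
    contamination: dict[str, float]
    seed: int
    cell_gates: dict[str, str] | None = None
    cell_true_types: dict[str, str] | None = None
    expected_type_per_gate: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for gate, frac in self.contamination.items():
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"contamination[{gate!r}] = {frac} outside [0, 1)")

    def to_json(self, dest: str | Path) -> None:
        document = {
            "marker_genes": {t: list(g) for t, g in self.marker_genes.items()},
            "planted_edges": sorted(list(e) for e in self.planted_edges),
            "contamination": self.contamination,
            "seed": self.seed,
            "cell_gates": self.cell_gates,
            "cell_true_types": self.cell_true_types,
            "expected_type_per_gate": self.expected_type_per_gate,
        }
        Path(dest).write_text(json.dumps(document, indent=1))

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticTruth":
        document = json.loads(Path(source).read_text())
        return cls(
            marker_genes={t: tuple(g) for t, g in document["marker_genes"].items()},
            planted_edges=frozenset(tuple(e) for e in document["planted_edges"]),
            contamination=document["contamination"],
            seed=document["seed"],
            cell_gates=document["cell_gates"],
            cell_true_types=document["cell_true_types"],
            expected_type_per_gate=document["expected_type_per_gate"],
        )


def _type_names(n_types: int, type_names: Sequence[str] | None) -> list[str]:
    if type_names is not None:
        if len(type_names) != n_types:
            raise ValueError(f"{len(type_names)} names for {n_types} types")
        return list(type_names)
    if n_types <= len(DEFAULT_TYPE_NAMES):
        return list(DEFAULT_TYPE_NAMES[:n_types])
    return list(DEFAULT_TYPE_NAMES) + [
        f"type{i}" for i in range(len(DEFAULT_TYPE_NAMES), n_types)
    ]


def _gene_universe(
    types: Sequence[str], n_genes: int, markers_per_type: int, planted_pairs: int
) -> tuple[dict[str, tuple[str, ...]], list[str], list[str], list[str]]:
    """Shared gene-naming scheme: markers, ligands, receptors, background."""
    n_structured = markers_per_type * len(types) + 2 * planted_pairs
    if n_structured > n_genes:
        raise ValueError(
            f"{n_structured} structured genes (markers + ligand/receptor pairs) "
            f"exceed the {n_genes}-gene universe"
        )
    markers = {
        t: tuple(f"Mk_{t}_{i + 1}" for i in range(markers_per_type)) for t in types
    }
    ligands = [f"Lig{i + 1:03d}" for i in range(planted_pairs)]
    receptors = [f"Rec{i + 1:03d}" for i in range(planted_pairs)]
    background = [f"Bg{i + 1:04d}" for i in range(n_genes - n_structured)]
    return markers, ligands, receptors, background


def generate_bulk(
    n_types: int = 4,
    n_genes: int = 300,
    markers_per_type: int = 10,
    planted_pairs: int = 20,
    base_fpkm: float = 20.0,
    noise_sd: float = 0.3,
    seed: int = 0,
    high_fold: float = 5.0,
    low_fold: float = 0.1,
    type_names: Sequence[str] | None = None,
) -> tuple[ExpressionProfile, LRDatabase, SyntheticTruth]:
    """Simulate a bulk FPKM table, LR catalogue and its planted truth.

    Each planted pair gets one sender and one receiver population (drawn
    uniformly, autocrine allowed): the ligand's FPKM is
    ``high_fold * EXPRESSION_THRESHOLD`` in the sender and
    ``low_fold * EXPRESSION_THRESHOLD`` elsewhere, and symmetrically for the
    receptor in the receiver. Markers follow the same high/low pattern in
    their own population. Background genes get one lognormal base level
    shared across populations (near-uniform profile). Every entry is then
    multiplied by ``exp(Normal(0, noise_sd))``; with ``noise_sd=0`` the
    expressed/silent pattern is deterministic and matches the truth exactly.
    """
    if n_genes <= 0 or markers_per_type < 0 or planted_pairs < 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    types = _type_names(n_types, type_names)
    markers, ligands, receptors, background = _gene_universe(
        types, n_genes, markers_per_type, planted_pairs
    )
    high = high_fold * EXPRESSION_THRESHOLD
    low = low_fold * EXPRESSION_THRESHOLD

    gene_order: list[str] = []
    rows: list[np.ndarray] = []
    for t in types:
        for gene in markers[t]:
            gene_order.append(gene)
            rows.append(np.where(np.array(types) == t, high, low))

    planted_edges: set[tuple[str, str, str, str]] = set()
    pairs: set[tuple[str, str]] = set()
    for lig, rec in zip(ligands, receptors):
        sender = types[rng.integers(n_types)]
        receiver = types[rng.integers(n_types)]
        planted_edges.add((lig, rec, sender, receiver))
        pairs.add((lig, rec))
        gene_order.append(lig)
        rows.append(np.where(np.array(types) == sender, high, low))
        gene_order.append(rec)
        rows.append(np.where(np.array(types) == receiver, high, low))

    base_levels = rng.lognormal(mean=np.log(base_fpkm), sigma=1.0, size=len(background))
    for gene, level in zip(background, base_levels):
        gene_order.append(gene)
        rows.append(np.full(n_types, level))

    values = np.vstack(rows) if rows else np.empty((0, n_types))
    if noise_sd > 0:
        values = values * rng.lognormal(mean=0.0, sigma=noise_sd, size=values.shape)
    profile = ExpressionProfile(pd.DataFrame(values, index=gene_order, columns=types))
    lrdb = LRDatabase(pairs=frozenset(pairs), source_tag=f"synthetic(seed={seed})")
    truth = SyntheticTruth(
        marker_genes=markers,
        planted_edges=frozenset(planted_edges),
        contamination={},
        seed=seed,
    )
    return profile, lrdb, truth


def generate_single_cell(
    n_types: int = 4,
    cells_per_gate: int = 200,
    depth_mean: float = 3000.0,
    depth_sd_log: float = 0.35,
    nb_dispersion: float = 2.0,
    contamination: float | Mapping[str, float] = 0.0,
    seed: int = 0,
    n_genes: int = 300,
    markers_per_type: int = 10,
    type_names: Sequence[str] | None = None,
) -> tuple[SingleCellMatrix, SyntheticTruth]:
    """Simulate gated single-cell transcript counts with planted identities.

    One FACS gate per population; each cell's true identity equals its gate
    with probability ``1 - contamination[gate]``, otherwise a uniformly
    drawn other type. Counts are negative-binomial (gamma-Poisson, common
    dispersion ``nb_dispersion``) around a type-specific mean profile scaled
    by a lognormal per-cell depth, so some cells fall below any chosen
    transcript-count filter. Gene names reuse the bulk generator's universe
    so marker panels transfer between the two.
    """
    rng = np.random.default_rng(seed)
    types = _type_names(n_types, type_names)
    if isinstance(contamination, Mapping):
        contam = {t: float(contamination.get(t, 0.0)) for t in types}
    else:
        contam = {t: float(contamination) for t in types}
    for gate, frac in contam.items():
        if not 0.0 <= frac < 1.0:
            raise ValueError(f"contamination[{gate!r}] = {frac} outside [0, 1)")
    if nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    markers, _, _, background = _gene_universe(types, n_genes, markers_per_type, 0)

    gene_order = [g for t in types for g in markers[t]] + background
    n_total = len(gene_order)
    # type-specific expression weights: own markers high, foreign markers
    # nearly silent, background shared lognormal level across types
    bg_levels = rng.lognormal(mean=0.0, sigma=0.5, size=len(background))
    weights = {}
    for t in types:
        w = np.empty(n_total)
        i = 0
        for t2 in types:
            block = slice(i, i + len(markers[t2]))
            w[block] = 30.0 if t2 == t else 0.05
            i += len(markers[t2])
        w[i:] = bg_levels
        weights[t] = w / w.sum()

    cell_ids: list[str] = []
    gates: dict[str, str] = {}
    true_types: dict[str, str] = {}
    columns: list[np.ndarray] = []
    for gate in types:
        others = [t for t in types if t != gate]
        for i in range(cells_per_gate):
            cell = f"{gate}_c{i + 1:04d}"
            if n_types > 1 and rng.random() < contam[gate]:
                identity = others[rng.integers(len(others))]
            else:
                identity = gate
            depth = rng.lognormal(mean=np.log(depth_mean), sigma=depth_sd_log)
            mu = depth * weights[identity]
            lam = rng.gamma(shape=nb_dispersion, scale=mu / nb_dispersion)
            counts = rng.poisson(lam)
            cell_ids.append(cell)
            gates[cell] = gate
            true_types[cell] = identity
            columns.append(counts)

    counts_frame = pd.DataFrame(
        np.column_stack(columns).astype(np.int64), index=gene_order, columns=cell_ids
    )
    matrix = SingleCellMatrix(
        counts=counts_frame, gate_labels=pd.Series(gates, name="gate")
    )
    truth = SyntheticTruth(
        marker_genes=markers,
        planted_edges=frozenset(),
        contamination=contam,
        seed=seed,
        cell_gates=gates,
        cell_true_types=true_types,
        expected_type_per_gate={t: t for t in types},
    )
    return matrix, truth


def thin_profile(
    profile: ExpressionProfile, midpoint: float = 50.0, seed: int = 0
) -> ExpressionProfile:
    """Apply expression-dependent dropout, emulating shallow detection.

    Each entry is retained with probability ``expr / (expr + midpoint)``
    (a saturating detection curve: strongly expressed genes are almost
    always seen, lowly expressed ones mostly drop to zero) and set to 0
    otherwise — the qualitative signature of single-cell versus deep bulk
    profiling.
    """
    rng = np.random.default_rng(seed)
    values = profile.values
    p_detect = values / (values + midpoint)
    detected = rng.random(values.shape) < p_detect
    thinned = np.where(detected, values, 0.0)
    return ExpressionProfile(
        pd.DataFrame(thinned, index=profile.gene_ids, columns=profile.type_ids)
    )
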