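"""Ligand-receptor interaction network inference from population profiles.

The pipeline mirrors the in-silico communication-mapping procedure used for
sorted brain populations: genes are kept when their arithmetic mean FPKM
across populations is strictly above a cutoff (10 FPKM by default); a gene
counts as "expressed" in a population when its FPKM there reaches a per-type
cutoff (the same 10 FPKM by default, configurable); a directed edge
(ligand, receptor, sender, receiver) exists whenever a catalogued pair has
its ligand expressed in the sender and its receptor in the receiver —
autocrine (sender == receiver) edges included. Enrichment of a gene in a
population is its expression divided by the gene's mean across all
populations, so enrichment averages to one by construction and a gene
expressed in exactly one of four populations scores 4 there.
"""

from __future__ import annotations

import difflib
import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_formats import ExpressionProfile, LRDatabase, ValidationError

logger = logging.getLogger("crosstalker")

STRENGTH_MODES = ("geomean", "min", "sum", "product")


class EdgeRecord(NamedTuple):
    """One directed interaction: ligand in sender acting on receptor in receiver."""

    ligand: str
    receptor: str
    sender: str
    receiver: str
    strength: float


@dataclass(frozen=True)
class EnrichmentMatrix:
    """Genes x populations expression-relative-to-mean scores."""

    scores: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def type_ids(self) -> list[str]:
        return list(self.scores.columns)


@dataclass(frozen=True)
class ExpressionCalls:
    """Boolean genes x populations matrix: is gene g expressed in type t?"""

    calls: pd.DataFrame
    per_type_min: float


@dataclass(frozen=True)
class InteractionNetwork:
    """A set of directed ligand-receptor edges over a declared population set."""

    edges: tuple[EdgeRecord, ...]
    populations: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pops = set(self.populations)
        for e in self.edges:
            if e.sender not in pops or e.receiver not in pops:
                raise ValidationError(
                    f"edge {e} references a population outside {sorted(pops)}"
                )
            if e.strength < 0:
                raise ValidationError(f"negative edge strength: {e}")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def unique_pair_count(self) -> int:
        """Distinct (ligand, receptor) gene pairs with at least one edge."""
        return len({(e.ligand, e.receptor) for e in self.edges})

    @property
    def pair_counts(self) -> dict[tuple[str, str], int]:
        """(sender, receiver) -> number of edges, all ordered combinations."""
        counts = {(s, r): 0 for s in self.populations for r in self.populations}
        for e in self.edges:
            counts[(e.sender, e.receiver)] += 1
        return counts


# ---------------------------------------------------------------------------
# Expression filtering and scoring
# ---------------------------------------------------------------------------


def filter_expressed_genes(profile: ExpressionProfile, min_mean: float = 10.0) -> ExpressionProfile:
    """Keep genes whose mean FPKM across populations is strictly > ``min_mean``.

    A gene sitting exactly at the cutoff is removed: the criterion is
    "average expression greater than" the threshold, not at it.
    """
    means = profile.data.mean(axis=1)
    kept = profile.data.loc[means > min_mean]
    logger.info(
        "mean-expression filter (> %g FPKM): kept %d / %d genes",
        min_mean, kept.shape[0], profile.n_genes,
    )
    if kept.shape[0] == 0:
        logger.warning("mean-expression filter removed every gene")
    return ExpressionProfile(kept)


def enrichment_scores(profile: ExpressionProfile) -> EnrichmentMatrix:
    """Score each gene's expression in each population relative to its mean.

    ``score(g, t) = expr(g, t) / mean_t' expr(g, t')``. Genes whose mean is
    zero (never detected) are dropped with a warning; for retained genes the
    scores average to exactly 1 across populations.
    """
    if profile.n_genes == 0:
        raise ValidationError("cannot score an empty expression profile")
    means = profile.data.mean(axis=1)
    zero = means == 0
    if zero.any():
        logger.warning("dropping %d genes with zero mean expression", int(zero.sum()))
    data = profile.data.loc[~zero]
    scores = data.div(means.loc[~zero], axis=0)
    return EnrichmentMatrix(scores=scores)


def call_expression(profile: ExpressionProfile, per_type_min: float = 10.0) -> ExpressionCalls:
    """Binarize expression: gene g is called in type t iff expr(g,t) >= cutoff.

    With ``per_type_min=0`` every entry is called (values are >= 0 by
    invariant); the cutoff used is recorded on the result.
    """
    calls = profile.data >= per_type_min
    return ExpressionCalls(calls=calls, per_type_min=per_type_min)


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


def edge_strength(
    ligand_fpkm: float, receptor_fpkm: float, mode: str = "geomean"
) -> float:
    """Scalar strength of one edge from its two absolute expression levels."""
    if mode == "geomean":
        return math.sqrt(ligand_fpkm * receptor_fpkm)
    if mode == "min":
        return min(ligand_fpkm, receptor_fpkm)
    if mode == "sum":
        return ligand_fpkm + receptor_fpkm
    if mode == "product":
        return ligand_fpkm * receptor_fpkm
    raise ValueError(f"unknown strength mode {mode!r}; choose from {STRENGTH_MODES}")


def build_network(
    profile: ExpressionProfile,
    lrdb: LRDatabase,
    per_type_min: float = 10.0,
    min_mean: float = 10.0,
    strength: str = "geomean",
    case_insensitive: bool = False,
) -> InteractionNetwork:
    """Infer the directed cell-cell communication network.

    An edge (L, R, s, r) is emitted for every catalogued pair (L, R) with L
    expressed in sender s and R expressed in receiver r (per-type cutoff on
    the mean-filtered profile); all ordered sender/receiver combinations,
    autocrine included, are evaluated. Catalogue genes absent from the
    profile are skipped with a summary count. Edge strength combines the
    ligand's FPKM in the sender with the receptor's FPKM in the receiver
    (geometric mean by default).
    """
    if len(lrdb) == 0:
        raise ValidationError("empty ligand-receptor database")
    if strength not in STRENGTH_MODES:
        raise ValueError(f"unknown strength mode {strength!r}; choose from {STRENGTH_MODES}")
    filtered = filter_expressed_genes(profile, min_mean=min_mean)
    calls = call_expression(filtered, per_type_min=per_type_min)
    data = filtered.data
    if case_insensitive:
        lookup = {g.casefold(): g for g in data.index}
        resolve = lambda symbol: lookup.get(symbol.casefold())
    else:
        present = set(data.index)
        resolve = lambda symbol: symbol if symbol in present else None

    populations = tuple(profile.type_ids)
    edges: list[EdgeRecord] = []
    skipped_pairs = 0
    for ligand, receptor in lrdb.sorted_pairs():
        lig = resolve(ligand)
        rec = resolve(receptor)
        if lig is None or rec is None:
            skipped_pairs += 1
            continue
        lig_row = data.loc[lig]
        rec_row = data.loc[rec]
        senders = [t for t in populations if calls.calls.at[lig, t]]
        receivers = [t for t in populations if calls.calls.at[rec, t]]
        for s in senders:
            for r in receivers:
                edges.append(
                    EdgeRecord(
                        ligand=lig,
                        receptor=rec,
                        sender=s,
                        receiver=r,
                        strength=edge_strength(float(lig_row[s]), float(rec_row[r]), strength),
                    )
                )
    if skipped_pairs:
        logger.info(
            "%d / %d catalogue pairs skipped (gene absent from filtered profile)",
            skipped_pairs, len(lrdb),
        )
    network = InteractionNetwork(
        edges=tuple(sorted(edges)),
        populations=populations,
        metadata={
            "min_mean": min_mean,
            "per_type_min": per_type_min,
            "strength": strength,
            "case_insensitive": case_insensitive,
            "catalogue_pairs": len(lrdb),
            "catalogue_pairs_skipped": skipped_pairs,
        },
    )
    logger.info(
        "network: %d directed edges, %d unique ligand-receptor pairs, %d populations",
        len(network), network.unique_pair_count, len(populations),
    )
    return network


def pairwise_count_table(network: InteractionNetwork) -> pd.DataFrame:
    """Sender x receiver table of edge counts (rows send, columns receive)."""
    pops = list(network.populations)
    table = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    for (s, r), count in network.pair_counts.items():
        table.at[s, r] = count
    table.index.name = "sender"
    table.columns.name = "receiver"
    return table


# ---------------------------------------------------------------------------
# Subnetworks and ranking
# ---------------------------------------------------------------------------


def subnetwork(
    network: InteractionNetwork,
    focus_gene: str,
    mode: str = "receptor-centric",
    enrichment: EnrichmentMatrix | None = None,
) -> tuple[InteractionNetwork, pd.DataFrame | None]:
    """Extract the edges centred on one receptor or one ligand.

    Receptor-centric keeps edges whose receptor is ``focus_gene``;
    ligand-centric keeps edges whose ligand is it. Returns the sub-network
    plus, when an enrichment matrix is supplied, the enrichment rows of all
    genes participating in the sub-network (the heatmap slice).
    """
    if mode not in ("receptor-centric", "ligand-centric"):
        raise ValueError(f"unknown subnetwork mode {mode!r}")
    genes = sorted({e.ligand for e in network.edges} | {e.receptor for e in network.edges})
    if focus_gene not in genes:
        near = difflib.get_close_matches(focus_gene, genes, n=3)
        raise KeyError(
            f"gene {focus_gene!r} not in network; close matches: {near or 'none'}"
        )
    attr = "receptor" if mode == "receptor-centric" else "ligand"
    edges = tuple(e for e in network.edges if getattr(e, attr) == focus_gene)
    if not edges:
        logger.warning("%s subnetwork of %s is empty", mode, focus_gene)
    sub = InteractionNetwork(
        edges=edges,
        populations=network.populations,
        metadata={**network.metadata, "focus_gene": focus_gene, "mode": mode},
    )
    heatmap = None
    if enrichment is not None:
        sub_genes = sorted({e.ligand for e in edges} | {e.receptor for e in edges})
        rows = [g for g in sub_genes if g in enrichment.scores.index]
        heatmap = enrichment.scores.loc[rows]
    return sub, heatmap


def rank_top_interactions(
    network: InteractionNetwork,
    enrichment: EnrichmentMatrix,
    n: int = 50,
    specificity_min: float = 2.0,
) -> list[EdgeRecord]:
    """Top-n edges by strength among those with a sender-specific ligand.

    An edge qualifies when its ligand's maximum enrichment across
    populations is at least ``specificity_min`` *and* that maximum is
    attained in the edge's sender — i.e. the ligand is most enriched where
    it is sent from, at least ``specificity_min``-fold its cross-population
    mean. Ties in strength break lexicographically on
    (ligand, receptor, sender, receiver) so output is reproducible.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    scores = enrichment.scores
    qualifying = []
    for e in network.edges:
        if e.ligand not in scores.index:
            continue
        row = scores.loc[e.ligand]
        peak = float(row.max())
        if peak >= specificity_min and float(row[e.sender]) >= peak - 1e-12:
            qualifying.append(e)
    ranked = sorted(qualifying, key=lambda e: (-e.strength, e.ligand, e.receptor, e.sender, e.receiver))
    return ranked[:n]
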