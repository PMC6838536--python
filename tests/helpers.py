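"""Independent oracles used across the suite.

These deliberately re-derive results by the most literal route possible
(triple loops, explicit recounts) and never call the code paths they
check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from crosstalker import ExpressionProfile, LRDatabase


def brute_force_edges(
    data: pd.DataFrame,
    pairs: set[tuple[str, str]],
    per_type_min: float = 10.0,
    min_mean: float = 10.0,
) -> set[tuple[str, str, str, str]]:
    """Exhaustive enumeration of directed edges, one loop level per factor."""
    kept = [g for g in data.index if sum(data.loc[g]) / data.shape[1] > min_mean]
    edges = set()
    for ligand, receptor in pairs:
        if ligand not in kept or receptor not in kept:
            continue
        for sender in data.columns:
            for receiver in data.columns:
                if data.at[ligand, sender] >= per_type_min and data.at[receptor, receiver] >= per_type_min:
                    edges.add((ligand, receptor, sender, receiver))
    return edges


def random_instance(
    rng: np.random.Generator,
    max_genes: int = 200,
    max_pairs: int = 50,
    max_types: int = 6,
) -> tuple[ExpressionProfile, LRDatabase]:
    """A random FPKM profile + catalogue, spanning both filter boundaries."""
    n_genes = int(rng.integers(5, max_genes + 1))
    n_types = int(rng.integers(2, max_types + 1))
    genes = [f"G{i}" for i in range(n_genes)]
    types = [f"T{i}" for i in range(n_types)]
    # mixture spanning values well below, around and above the 10-FPKM cutoffs
    values = rng.choice(
        [0.0, 1.0, 5.0, 10.0, 12.0, 50.0, 200.0],
        size=(n_genes, n_types),
        p=[0.25, 0.15, 0.15, 0.1, 0.15, 0.1, 0.1],
    )
    profile = ExpressionProfile(pd.DataFrame(values, index=genes, columns=types))
    n_pairs = int(rng.integers(1, max_pairs + 1))
    pairs = set()
    while len(pairs) < n_pairs:
        lig, rec = rng.choice(n_genes, size=2, replace=True)
        pairs.add((genes[lig], genes[rec]))
    return profile, LRDatabase(pairs=frozenset(pairs))
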