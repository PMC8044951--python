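"""Hypergeometric over-representation analysis of modules against gene sets.

Standard ORA: for a query of n genes drawn from a universe of N, of which K
belong to a given set, the enrichment p-value is the upper hypergeometric
tail P(X >= k) of the observed overlap k. BH-FDR is applied separately
within each query's family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .deg import bh_adjust
from .mcl import Module

__all__ = [
    "GeneSetCollection",
    "hypergeom_upper_tail",
    "enrich_gene_list",
    "enrich_modules",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (a GMT collection) with an optional explicit universe."""

    name: str
    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        members = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        self.universe = frozenset(self.universe) | members


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): the ORA enrichment p-value.

    k = overlap, K = set size in universe, n = query size in universe,
    N = universe size.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_gene_list(
    query_id: str,
    genes,
    collection: GeneSetCollection,
    measured=None,
    universe_mode: str = "measured",
) -> pd.DataFrame:
    """ORA of one gene list against every set in the collection.

    The universe defaults to measured genes that appear in the collection
    (``universe_mode="measured"``, requires ``measured``); with
    ``"collection"`` it is the union of all collection sets. Only sets with
    overlap >= 1 produce records; q-values are BH within this query.
    """
    if not collection.sets:
        raise ValueError("empty gene-set collection")
    if universe_mode == "measured":
        if measured is None:
            raise ValueError("universe_mode='measured' requires the measured gene list")
        universe = frozenset(measured) & collection.universe
    elif universe_mode == "collection":
        universe = collection.universe
    else:
        raise ValueError(f"unknown universe_mode {universe_mode!r}")

    query = frozenset(genes) & universe
    rows = []
    for set_name in sorted(collection.sets):
        members = collection.sets[set_name] & universe
        overlap = query & members
        if not overlap:
            continue
        p = hypergeom_upper_tail(len(overlap), len(members), len(query), len(universe))
        rows.append(
            (query_id, set_name, len(overlap), len(members), len(query), len(universe), p)
        )
    df = pd.DataFrame(
        rows, columns=["query_id", "set_name", "k", "K", "n", "N", "p"]
    )
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df.sort_values(["q", "p", "set_name"]).reset_index(drop=True)


def enrich_modules(
    modules: list[Module],
    collection: GeneSetCollection,
    measured=None,
    min_module_size: int = 7,
    fdr_max: float = 0.05,
    universe_mode: str = "measured",
) -> pd.DataFrame:
    """ORA of each sufficiently large module, adjusted per module.

    Modules smaller than ``min_module_size`` are skipped. Records are
    flagged ``significant`` when q < ``fdr_max``; the BH family is each
    module's own set of tests.
    """
    frames = []
    for m in modules:
        if m.size < min_module_size:
            continue
        frames.append(
            enrich_gene_list(
                f"module_{m.module_id}", m.genes, collection, measured, universe_mode
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["query_id", "set_name", "k", "K", "n", "N", "p", "q", "significant"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["q"] < fdr_max
    return out
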