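"""Directional over-representation analysis (ORA) over GMT collections.

Up- and down-regulated DEGs are tested separately against each gene set
with the hypergeometric upper tail, and BH-corrected within each
(collection x direction) stratum, yielding a two-column (up/down)
heatmap-ready table. The universe is the set of genes that entered the
meta-analysis, not the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .meta import bh_adjust


@dataclass
class EnrichmentResult:
    set_name: str
    direction: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p: float
    fdr: float | None = None


def hypergeom_pvalue(overlap: int, set_size: int, query_size: int,
                     universe_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(universe, set, query)."""
    if universe_size <= 0:
        raise ValueError("empty universe")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size,
                                    query_size))


def hypergeom_ora(query, gene_set, universe) -> EnrichmentResult:
    """One-sided enrichment of ``query`` in ``gene_set`` within ``universe``.

    The gene set is intersected with the universe before testing; the
    query must already be a subset of the universe.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    gs = set(gene_set) & universe
    overlap = len(query & gs)
    p = hypergeom_pvalue(overlap, len(gs), len(query), len(universe))
    return EnrichmentResult(set_name="", direction="", overlap=overlap,
                            set_size=len(gs), query_size=len(query),
                            universe_size=len(universe), p=p)


def enrich_directional(deg_table: pd.DataFrame, collection: GeneSetCollection,
                       universe) -> pd.DataFrame:
    """Test a collection against up-DEGs and down-DEGs separately.

    ``deg_table`` is a DEG table indexed by gene with a ``direction``
    column. BH correction is applied within each direction stratum.
    Returns a long-format DataFrame sortable into an up/down heatmap.
    """
    universe = set(universe)
    rows: list[EnrichmentResult] = []
    for direction in ("up", "down"):
        query = set(deg_table.index[deg_table["direction"] == direction])
        query &= universe
        stratum: list[EnrichmentResult] = []
        if query:
            for name, members in collection:
                res = hypergeom_ora(query, members, universe)
                res.set_name = name
                res.direction = direction
                stratum.append(res)
            fdrs = bh_adjust([r.p for r in stratum])
            for r, f in zip(stratum, fdrs):
                r.fdr = float(f)
        rows.extend(stratum)
    return pd.DataFrame([vars(r) for r in rows])


def heatmap_table(enrichment: pd.DataFrame, value: str = "fdr") -> pd.DataFrame:
    """Pivot long-format enrichment into sets x (up, down) for heatmaps."""
    if enrichment.empty:
        return pd.DataFrame(columns=["up", "down"])
    wide = enrichment.pivot(index="set_name", columns="direction", values=value)
    return wide.reindex(columns=["up", "down"])
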