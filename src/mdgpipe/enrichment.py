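"""Local over-representation analysis against user-supplied gene sets.

Upper-tail hypergeometric test of a query gene set against each annotated
set, restricted to a common universe (by default the genes surviving
preprocessing).  Results are filtered at a raw p-value threshold (default
0.01); BH-adjusted values are reported alongside for reference.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def ora_test(query, geneset, universe) -> float:
    """P(X >= overlap) for overlap under hypergeometric(|U|, |S|, |Q|)."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    if not query:
        raise ValueError("empty query (after restriction to the universe)")
    geneset = set(geneset) & universe
    overlap = len(query & geneset)
    return float(hypergeom.sf(overlap - 1, len(universe), len(geneset), len(query)))


def enrich(query, collection: Mapping[str, set], universe, alpha: float = 0.01,
           min_set_size: int = 1) -> pd.DataFrame:
    """ORA of ``query`` against every set in ``collection``.

    Sets are restricted to the universe first; sets that become smaller than
    ``min_set_size`` are dropped with a warning.  Returns rows sorted by p,
    filtered strictly at ``p < alpha``; ``fdr`` is BH across all tested sets
    (computed before the alpha filter).
    """
    universe = set(universe)
    query = set(query) & universe
    rows = []
    for name, members in collection.items():
        restricted = set(members) & universe
        if len(restricted) < min_set_size:
            warnings.warn(f"gene set {name!r} empty after universe restriction",
                          stacklevel=2)
            continue
        overlap = len(query & restricted)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(restricted), len(query)))
        rows.append({"set": name, "overlap": overlap, "set_size": len(restricted),
                     "p": p})
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    if len(table):
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["p", "set"], ignore_index=True)
        if alpha < 1:  # strict raw-p filter; alpha=1 disables filtering
            table = table[table["p"] < alpha].reset_index(drop=True)
    else:
        table["fdr"] = []
    return table
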