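"""Local hypergeometric over-representation analysis (ORA).

Given a query gene set (e.g. the mRNAs of a ceRNA network or of one key
lncRNA's sub-network), a gene-set collection (GMT) and a background
universe, each set is tested with the hypergeometric upper tail
P(X >= k), where k is the overlap, K the set size within the universe, n
the query size and N the universe size. The significance flag uses the
raw p-value at ``alpha`` (the conventional ORA screen); BH-adjusted
p-values are always reported alongside because raw-p screening inflates
findings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import GeneSetCollection, ValidationError

logger = logging.getLogger(__name__)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Probability of drawing at least ``k`` members of a ``K``-gene set when
    sampling ``n`` genes without replacement from a universe of ``N``.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValidationError(f"invalid hypergeometric bounds: k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(query, collection: GeneSetCollection, universe,
           alpha: float = 0.05) -> pd.DataFrame:
    """Test every gene set with overlap >= 1 against the query.

    Query genes outside the universe are dropped with a logged count; set
    members outside the universe do not count toward K. Results are sorted
    by p-value ascending then set id.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.info("enrich: dropping %d query genes outside the universe", len(outside))
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for gs in collection:
        members = gs.genes & universe
        overlap = sorted(query & members)
        k, K = len(overlap), len(members)
        if k == 0:
            continue
        rows.append({
            "set_id": gs.set_id, "description": gs.description,
            "k": k, "K": K, "n": n, "N": N,
            "pvalue": hypergeom_upper_tail(k, K, n, N),
            "genes": ",".join(overlap),
        })
    df = pd.DataFrame(rows, columns=["set_id", "description", "k", "K", "n", "N",
                                     "pvalue", "genes"])
    if len(df):
        df["adj_pvalue"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
    else:
        df["adj_pvalue"] = pd.Series(dtype=float)
    df["significant"] = df["pvalue"] < alpha
    return df.sort_values(["pvalue", "set_id"]).reset_index(drop=True)
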