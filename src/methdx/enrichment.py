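"""Over-representation analysis of a query gene set against GMT collections.

A generic hypergeometric ORA: for each gene set, the p-value is the
upper-tail probability P(X >= k) of drawing at least the observed overlap k
when |query| genes are sampled without replacement from a universe containing
|set| members of the set. P-values are BH-adjusted across sets and a set is
flagged enriched when adj_p < alpha. Term databases are the caller's
responsibility; any GMT file works, including synthetic ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets restricted to a universe; empty sets are dropped."""

    sets: dict  # set_id -> (name, frozenset of members)
    universe: frozenset

    @classmethod
    def from_sets(cls, sets: dict, universe: set) -> "GeneSetCollection":
        if not universe:
            raise ValueError("universe must be non-empty")
        universe = frozenset(universe)
        restricted = {}
        for set_id, (name, members) in sets.items():
            kept = frozenset(members) & universe
            if kept:
                restricted[set_id] = (name, kept)
            else:
                logger.warning("dropping gene set %s: no members in universe", set_id)
        return cls(sets=restricted, universe=universe)

    @classmethod
    def from_gmt(cls, path: str | Path, universe: set | None = None) -> "GeneSetCollection":
        """Read a GMT file (per line: id, description, members, tab-separated).

        With ``universe=None`` the universe is the union of all members.
        """
        sets = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            set_id, name, members = fields[0], fields[1], [g for g in fields[2:] if g]
            sets[set_id] = (name, frozenset(members))
        if universe is None:
            universe = set().union(*(m for _, m in sets.values())) if sets else set()
        return cls.from_sets(sets, universe)


def ora_hypergeometric(
    query: set, collection: GeneSetCollection, alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric over-representation test of ``query`` against each set.

    Query genes outside the universe are logged and dropped. Returns a
    DataFrame indexed by set_id with columns ``name``, ``set_size``,
    ``overlap``, ``p_value``, ``adj_p``, ``enriched``.
    """
    if not collection.universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - collection.universe
    if outside:
        logger.warning("dropping %d query genes outside the universe", len(outside))
        query &= collection.universe
    if not query:
        logger.warning("empty query after universe restriction: all p-values are 1")

    M = len(collection.universe)
    N = len(query)
    rows = []
    for set_id, (name, members) in sorted(collection.sets.items()):
        n = len(members)
        k = len(query & members)
        # P(X >= k) with X ~ Hypergeom(M, n, N); sf(k-1) is the upper tail.
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if N else 1.0
        rows.append((set_id, name, n, k, float(np.clip(p, np.nextafter(0.0, 1.0), 1.0))))
    table = pd.DataFrame(
        rows, columns=["set_id", "name", "set_size", "overlap", "p_value"]
    ).set_index("set_id")
    table["adj_p"] = bh_adjust(table["p_value"].to_numpy()) if len(table) else []
    table["enriched"] = table["adj_p"] < alpha
    return table
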