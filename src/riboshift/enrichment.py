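"""Gene-set over-representation by the hypergeometric test.

Given a query set (here, typically the enhanced-TE transcripts), a gene-set
collection (GMT) and a universe (all transcripts tested, not the genome),
each set is scored with the upper-tail hypergeometric probability

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

where N is the universe size, K the set size within the universe, n the
query size and k the observed overlap.  BH FDR across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .te import bh_fdr

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeometric_enrichment",
]


@dataclass
class GeneSetCollection:
    """Named gene sets; members are de-duplicated, optionally case-normalized."""

    sets: dict

    def restrict(self, universe) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping sets that become
        empty (with a warning)."""
        universe = set(universe)
        restricted, dropped = {}, []
        for name, members in self.sets.items():
            kept = set(members) & universe
            if kept:
                restricted[name] = kept
            else:
                dropped.append(name)
        if dropped:
            warnings.warn(f"dropped {len(dropped)} set(s) with no member in the universe")
        return GeneSetCollection(restricted)


def read_gmt(path, normalize_case: bool = True) -> GeneSetCollection:
    """Read a GMT file (per line: set name, description, members, tab
    separated).  Lines with fewer than three fields are an error."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {lineno}: expected >= 3 "
                                 f"tab-separated fields, got {len(fields)}")
            name = fields[0]
            members = fields[2:]
            if normalize_case:
                members = [m.upper() for m in members]
            sets[name] = set(members)
    return GeneSetCollection(sets)


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description] + sorted(members)) + "\n")


def hypergeometric_enrichment(query, collection, universe,
                              min_set_size: int = 5, max_set_size: int = 2000) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    Query members outside the universe are dropped with a warning (an empty
    query after restriction is an error); sets are restricted to the universe
    and those outside [min_set_size, max_set_size] are skipped.  Returns one
    row per retained set with k, K, n, N, fold_enrichment = (k/n)/(K/N),
    p_value and BH fdr, sorted by p.
    """
    universe = set(universe)
    query = set(query)
    stray = query - universe
    if stray:
        warnings.warn(f"dropped {len(stray)} query member(s) outside the universe")
        query &= universe
    if not query:
        raise ValueError("query is empty after restriction to the universe")
    if isinstance(collection, GeneSetCollection):
        sets = collection.sets
    else:
        sets = dict(collection)

    n = len(query)
    big_n = len(universe)
    rows = []
    for name, members in sets.items():
        members = set(members) & universe
        big_k = len(members)
        if not min_set_size <= big_k <= max_set_size:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({
            "set_name": name,
            "k": k,
            "K": big_k,
            "n": n,
            "N": big_n,
            "fold_enrichment": (k / n) / (big_k / big_n),
            "p_value": min(p, 1.0),
        })
    result = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N",
                                         "fold_enrichment", "p_value"])
    if len(result):
        result["fdr"] = bh_fdr(result["p_value"].to_numpy())
        result = result.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    else:
        result["fdr"] = []
    return result
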