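"""Over-representation analysis by hypergeometric test.

Stands in for DAVID/ClueGO-style enrichment: for a query gene set and a
collection of annotated gene sets, each term is scored with the
hypergeometric upper tail P(X >= k) for the overlap k between query and
term within a background universe, then Benjamini–Hochberg adjusted over
all tested terms.  Unless an explicit universe is supplied, the
background is the union of all collection members (DAVID-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "hypergeometric_p",
    "enrich",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSet:
    term_id: str
    description: str
    genes: set[str]


@dataclass
class GeneSetCollection:
    """Gene-set collection with an explicit background universe.

    When ``universe`` is empty at construction it defaults to the union
    of all term members.
    """

    terms: list[GeneSet] = field(default_factory=list)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValueError("term_ids must be unique")
        if not self.universe:
            for t in self.terms:
                self.universe |= t.genes

    def __len__(self) -> int:
        return len(self.terms)


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the annotated genes among ``n`` drawn from a universe of
    ``N`` genes of which ``K`` are annotated.  Computed via the survival
    function (log-space internally), so small tails are stable.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N; got k={k}, K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    p_max: float = 0.05,
    adjust: bool = True,
) -> pd.DataFrame:
    """Score every term of the collection against a query gene set.

    The query is restricted to the universe before testing; terms with no
    overlap (k = 0) are not tested.  Returns the full table sorted
    ascending by p with columns ``term_id, description, k, K, n, N, p, q,
    significant``, where ``significant`` flags rows with
    ``(q if adjust else p) < p_max``.
    """
    if not collection.universe:
        raise ValueError("enrichment requires a non-empty universe")
    universe = collection.universe
    query_set = {str(g) for g in query} & universe
    n, N = len(query_set), len(universe)
    rows = []
    for term in collection.terms:
        members = term.genes & universe
        k = len(query_set & members)
        if k < 1:
            continue
        K = len(members)
        rows.append((term.term_id, term.description, k, K, n, N, hypergeometric_p(k, K, n, N)))
    df = pd.DataFrame(rows, columns=["term_id", "description", "k", "K", "n", "N", "p"])
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
    df["q"] = q
    df["significant"] = (df["q"] if adjust else df["p"]) < p_max
    return df.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GMT format: term <tab> description <tab> gene1 <tab> gene2 ...

def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in collection.terms:
            fh.write("\t".join([t.term_id, t.description, *sorted(t.genes)]) + "\n")


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    terms = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            terms.append(GeneSet(parts[0], parts[1], {g for g in parts[2:] if g}))
    return GeneSetCollection(terms=terms, universe=set(universe) if universe else set())
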