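"""Gene-set overrepresentation analysis (ORA).

For a list of hit genes drawn from an annotated background universe,
each gene set is tested with a one-tailed hypergeometric test — the
probability of observing at least the seen overlap when the hit list is
drawn at random from the universe — and the resulting p-values are
Benjamini-Hochberg adjusted across sets.  A set is called significantly
overrepresented at ``q <= 0.05``.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from regenchron.io import GeneSetCollection


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    *N* genes in the universe, *K* of them in the set, *n* drawn as
    hits, *k* of the hits landing in the set.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    hit_genes: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Iterable[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Test every gene set for overrepresentation among *hit_genes*.

    The universe should be the deduplicated set of annotated genes on
    the platform; hits are intersected with it before testing.  Sets
    with no member in the universe are excluded.  Returns one row per
    tested set with counts, ``p_value``, ``q_value`` and a
    ``significant`` flag, sorted by p-value (ties by term id).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    if len(gene_sets) == 0:
        raise ValueError("empty gene-set collection")
    hits = set(hit_genes) & universe_set
    if set(hit_genes) and not hits:
        warnings.warn("hit list is disjoint from the universe; no tests performed")
    N, n = len(universe_set), len(hits)

    rows = []
    for s in gene_sets:
        members = s.members & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & hits)
        rows.append(
            {
                "term_id": s.term_id,
                "term_name": s.term_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeometric_test(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "k", "K", "n", "N", "p_value", "q_value", "significant"]
        )
    table = pd.DataFrame(rows)
    table["q_value"] = bh_adjust(table["p_value"])
    table["significant"] = table["q_value"] <= q_threshold
    return table.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)


def probes_to_genes(probe_ids: Iterable[str], annotation: pd.DataFrame) -> set[str]:
    """Collapse a probe list to gene symbols (a gene hits if any probe does)."""
    ann = annotation.set_index("probe_id")["gene_symbol"]
    hits = ann.reindex(list(probe_ids)).dropna()
    return set(hits)


def annotated_universe(annotation: pd.DataFrame) -> set[str]:
    """All gene symbols with at least one annotated probe on the platform."""
    return set(annotation["gene_symbol"].dropna())
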