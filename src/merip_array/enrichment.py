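"""Flat gene-set over-representation analysis.

For a selected gene list against a universe of size ``N`` and a term with
``K`` members in the universe, with ``n`` selected genes and ``k`` of them in
the term, the fold enrichment is ``(k/n)/(K/N)`` and the one-sided p-value is
the hypergeometric upper tail ``P(X >= k)`` (the one-sided Fisher exact test
on the 2x2 selection-by-membership table).  p-values are BH-adjusted across
terms.  The term hierarchy of ontology databases is deliberately not modelled:
each term is tested independently against the flat universe.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import GeneSetCollection
from .errors import AnalysisError
from .differential import bh_adjust


def _normalize_symbols(genes) -> list[str]:
    return [str(g).strip().upper() for g in genes if str(g).strip()]


def enrich_sets(
    selected,
    sets: GeneSetCollection,
    universe,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in ``selected``.

    Selected genes outside the universe are dropped with a warning; each set
    is intersected with the universe and sets that end up empty are skipped.
    Returns a frame indexed by set name with columns k, n, K, N,
    fold_enrichment, p, fdr, sorted by ascending p (ties by name).
    """
    uni = set(_normalize_symbols(universe))
    if not uni:
        raise AnalysisError("empty gene universe")
    sel = set(_normalize_symbols(selected))
    outside = sel - uni
    if outside:
        warnings.warn(
            f"{len(outside)} selected gene(s) outside the universe were dropped",
            stacklevel=2)
        sel &= uni
    N, n = len(uni), len(sel)

    rows = []
    for name, (_desc, members) in sets.items():
        term = set(_normalize_symbols(members)) & uni
        K = len(term)
        if K == 0:
            continue
        k = len(sel & term)
        fold = (k / n) / (K / N) if n else 0.0
        # upper tail P(X >= k): survival function at k-1
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append((name, k, n, K, N, fold, min(max(p, np.finfo(float).tiny), 1.0)))
    if not rows:
        return pd.DataFrame(
            columns=["k", "n", "K", "N", "fold_enrichment", "p", "fdr"])
    out = pd.DataFrame(
        rows, columns=["set_name", "k", "n", "K", "N", "fold_enrichment", "p"]
    ).set_index("set_name")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "set_name"], kind="mergesort")


def intersect_gene_list(genes, curated) -> list[str]:
    """Case-normalized intersection of a gene list with a curated list, sorted."""
    if not list(genes) or not list(curated):
        raise AnalysisError("both gene lists must be nonempty")
    return sorted(set(_normalize_symbols(genes)) & set(_normalize_symbols(curated)))
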