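"""One-sided hypergeometric over-representation of functional terms.

For a candidate gene set of size n drawn from a universe of N annotated genes,
a term annotating K universe genes and k candidates is scored with the upper
hypergeometric tail p = P(X >= k), X ~ Hypergeom(N, K, n) — identical to the
one-sided Fisher exact test on the 2x2 table. No multiple-testing correction
is applied to the ranking; an optional BH-FDR column can be emitted but never
filters results. Terms smaller than ``min_term_size`` are excluded before
testing, and a display p-value threshold affects reporting only.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require K <= N and n <= N, got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def read_term_map(
    path: str | Path, names_path: str | Path | None = None
) -> tuple[dict[str, set[str]], dict[str, dict[str, str]]]:
    """Read a 2-column (gene_id, term_id) TSV into term -> gene-set.

    ``names_path`` optionally maps term_id to (name, namespace) columns.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"], dtype=str)
    term_map: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        term_map.setdefault(term, set()).add(gene)
    meta: dict[str, dict[str, str]] = {}
    if names_path is not None:
        nd = pd.read_csv(
            names_path, sep="\t", header=None, names=["term_id", "name", "namespace"], dtype=str
        )
        meta = {
            t: {"name": n, "namespace": s}
            for t, n, s in zip(nd["term_id"], nd["name"], nd["namespace"])
        }
    return term_map, meta


def enrich_terms(
    candidates: Iterable[str],
    term_map: Mapping[str, set[str]],
    universe: Iterable[str] | None = None,
    term_meta: Mapping[str, Mapping[str, str]] | None = None,
    min_term_size: int = 5,
    display_p: float = 0.10,
) -> pd.DataFrame:
    """Rank terms by upper-tail hypergeometric p over a candidate gene set.

    The universe defaults to all genes annotated with any term in ``term_map``
    (per-namespace universes are obtained by passing a namespace-restricted
    term map). Candidates outside the universe are dropped with a logged
    count. The ``displayed`` column marks p < ``display_p`` for reporting; it
    never filters the table.
    """
    if universe is None:
        universe = set().union(*term_map.values()) if term_map else set()
    universe = set(universe)
    candidates = list(dict.fromkeys(candidates))
    in_universe = [g for g in candidates if g in universe]
    dropped = len(candidates) - len(in_universe)
    if dropped:
        logger.info("dropped %d candidate genes outside the annotated universe", dropped)
    cand = set(in_universe)
    if not cand:
        logger.warning("no candidate genes intersect the universe; empty result")
    N = len(universe)
    n = len(cand)

    rows = []
    for term, genes in term_map.items():
        term_genes = genes & universe
        K = len(term_genes)
        if K < min_term_size:
            continue
        k = len(term_genes & cand)
        p = hypergeom_tail(k, K, n, N) if n > 0 else 1.0
        meta = (term_meta or {}).get(term, {})
        rows.append(
            {
                "term_id": term,
                "name": meta.get("name", ""),
                "namespace": meta.get("namespace", ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "name", "namespace", "k", "K", "n", "N", "p_value"]
    )
    if len(out):
        out["fdr_bh"] = bh_fdr(out["p_value"].to_numpy())
        out["displayed"] = out["p_value"] < display_p
        out = out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        out["fdr_bh"] = pd.Series(dtype=float)
        out["displayed"] = pd.Series(dtype=bool)
    return out
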