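"""GO term over-representation among candidate gene sets.

Classic one-sided Fisher's exact test per GO term on the 2x2 table
(gene in test set x gene annotated with the term), restricted to terms
with at least ``min_genes`` annotated genes in the universe.  An optional
``elim`` mode walks terms most-specific-first along a supplied parent
edge list, removing the genes of already-significant child terms from
their ancestors to soften the hierarchy's double counting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("msgea")


def read_go_map(path) -> pd.DataFrame:
    """Gene-to-GO TSV with columns gene_id, go_id, namespace."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("gene_id", "go_id", "namespace") if c not in df.columns]
    if missing:
        raise ValueError(f"GO map lacks columns: {missing}")
    return df


def fisher_enrichment(
    test_genes,
    universe_genes,
    go_map: pd.DataFrame,
    min_genes: int = 5,
    alpha: float = 0.05,
    mode: str = "classic",
    ontology_edges: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-term one-sided Fisher enrichment of ``test_genes`` in the universe.

    Returns the full table (term, namespace, annotated, in_test, expected,
    p, significant) ranked by p; ``significant`` marks terms with
    p < ``alpha``.  Terms annotating fewer than ``min_genes`` universe
    genes are excluded outright.  ``mode='elim'`` requires
    ``ontology_edges`` with columns (child, parent).
    """
    test = set(test_genes)
    universe = set(universe_genes)
    if not test <= universe:
        raise ValueError("test genes must be a subset of the universe")
    columns = ["go_id", "namespace", "annotated", "in_test", "expected", "p", "significant"]
    if not test:
        logger.warning("fisher_enrichment: empty test set")
        return pd.DataFrame(columns=columns)
    gm = go_map[go_map["gene_id"].isin(universe)]
    ann: dict[str, set] = {
        go: set(grp["gene_id"]) for go, grp in gm.groupby("go_id", sort=True)
    }
    ns = gm.drop_duplicates("go_id").set_index("go_id")["namespace"]
    terms = [go for go, genes in ann.items() if len(genes) >= min_genes]

    if mode == "elim":
        if ontology_edges is None:
            raise ValueError("elim mode needs an ontology edge list (child, parent)")
        order = _specificity_order(terms, ontology_edges)
        removed: dict[str, set] = {go: set() for go in terms}
    elif mode == "classic":
        order = terms
    else:
        raise ValueError(f"unknown mode {mode!r}")

    N = len(universe)
    n_test = len(test)
    rows = []
    sig_genes_by_term: dict[str, set] = {}
    for go in order:
        genes = ann[go]
        if mode == "elim":
            genes = genes - removed[go]
            if len(genes) < min_genes:
                continue
        k = len(genes & test)
        K = len(genes)
        table = [[k, n_test - k], [K - k, (N - n_test) - (K - k)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "go_id": go,
                "namespace": ns.get(go, "BP"),
                "annotated": K,
                "in_test": k,
                "expected": n_test * K / N,
                "p": float(p),
                "significant": p < alpha,
            }
        )
        if mode == "elim" and p < alpha:
            sig_genes_by_term[go] = genes
            for anc in _ancestors(go, ontology_edges):
                if anc in removed:
                    removed[anc] |= genes
    out = pd.DataFrame(rows, columns=columns)
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def _ancestors(term: str, edges: pd.DataFrame) -> set:
    parents = edges.groupby("child")["parent"].apply(set).to_dict()
    seen: set = set()
    stack = list(parents.get(term, ()))
    while stack:
        t = stack.pop()
        if t not in seen:
            seen.add(t)
            stack.extend(parents.get(t, ()))
    return seen


def _specificity_order(terms, edges: pd.DataFrame) -> list:
    """Terms sorted most-specific-first (descendants before ancestors)."""
    depth = {t: len(_ancestors(t, edges)) for t in terms}
    return sorted(terms, key=lambda t: (-depth[t], t))
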