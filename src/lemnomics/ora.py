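"""Overrepresentation analysis against a custom gene -> GO annotation.

One-sided hypergeometric (upper-tail) test of a gene set's annotation counts
against a universe, with Benjamini-Hochberg correction across the tested
terms. Optionally closes each gene's annotation over is_a/part_of ancestors
from a GO OBO graph before counting.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from lemnomics.annotation import AnnotationDB

logger = logging.getLogger(__name__)

ORA_COLUMNS = (
    "go_id", "term_name", "k", "n", "K", "N",
    "gene_ratio", "bg_ratio", "pvalue", "padj", "member_genes",
)


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a draw of n from a universe of N genes of
    which K carry the annotation.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(
            f"invalid hypergeometric bounds: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order preserved, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def load_obo_ancestors(obo_path: str | Path) -> dict[str, set[str]]:
    """Map each GO term to its is_a/part_of ancestor closure (term excluded)."""
    import networkx as nx
    import obonet

    graph = obonet.read_obo(str(obo_path))
    keep = nx.MultiDiGraph()
    keep.add_nodes_from(graph.nodes)
    for child, parent, rel in graph.edges(keys=True):
        if rel in {"is_a", "part_of"}:
            keep.add_edge(child, parent)
    # edges point child -> parent, so ancestors are descendants in the graph
    return {term: set(nx.descendants(keep, term)) for term in keep.nodes}


def _propagate(gene2go: Mapping[str, set[str]], ancestors: Mapping[str, set[str]]) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for gene, terms in gene2go.items():
        closed = set(terms)
        for t in terms:
            closed |= ancestors.get(t, set())
        out[gene] = closed
    return out


def run_ora(
    gene_set: Iterable[str],
    universe: Iterable[str],
    annodb: AnnotationDB | Mapping[str, set[str]],
    min_size: int = 10,
    max_size: int = 500,
    propagate: bool = False,
    obo: str | Path | None = None,
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric overrepresentation analysis of a gene set.

    The test counts only annotated genes: n is the number of set genes with
    any GO annotation, N the number of annotated universe genes, K and k the
    universe/set genes carrying a given term. One row per term with
    ``min_size <= K <= max_size``; rows sorted by p-value (ties by term id);
    padj by BH across the tested terms. Unannotated genes are dropped with
    their count reported in ``DataFrame.attrs``.
    """
    gene2go = annodb.gene_to_go() if isinstance(annodb, AnnotationDB) else dict(annodb)
    names: dict[str, str] = dict(term_names or {})
    if propagate:
        if obo is None:
            raise ValueError("propagation requires an OBO file")
        ancestors = load_obo_ancestors(obo)
        gene2go = _propagate(gene2go, ancestors)
    if obo is not None and not names:
        import obonet

        graph = obonet.read_obo(str(obo))
        names = {t: d.get("name", "") for t, d in graph.nodes(data=True)}

    universe = set(universe)
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    annotated_universe = sorted(
        g for g in universe if gene2go.get(g)
    )
    annotated_set = [g for g in annotated_universe if g in gene_set]
    n_dropped_universe = len(universe) - len(annotated_universe)
    n_dropped_set = len(gene_set) - len(annotated_set)
    if n_dropped_universe:
        logger.info(
            "%d universe gene(s) without annotation dropped (%d from the gene set)",
            n_dropped_universe, n_dropped_set,
        )
    N, n = len(annotated_universe), len(annotated_set)

    empty = pd.DataFrame(columns=list(ORA_COLUMNS))
    empty.attrs["n_dropped_universe"] = n_dropped_universe
    empty.attrs["n_dropped_set"] = n_dropped_set
    if n == 0:
        logger.warning("no annotated genes in the gene set; empty ORA result")
        return empty

    term_universe: dict[str, set[str]] = {}
    for g in annotated_universe:
        for t in gene2go[g]:
            term_universe.setdefault(t, set()).add(g)
    rows = []
    for term in sorted(term_universe):
        members_universe = term_universe[term]
        K = len(members_universe)
        if K < min_size or K > max_size:
            continue
        members = sorted(g for g in annotated_set if g in members_universe)
        k = len(members)
        rows.append(
            {
                "go_id": term,
                "term_name": names.get(term, ""),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "gene_ratio": k / n,
                "bg_ratio": K / N,
                "pvalue": hypergeom_upper(k, n, K, N),
                "member_genes": ",".join(members),
            }
        )
    if not rows:
        return empty
    df = pd.DataFrame(rows)
    df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    df = df.sort_values(["pvalue", "go_id"], kind="mergesort").reset_index(drop=True)
    df = df[list(ORA_COLUMNS)]
    df.attrs["n_dropped_universe"] = n_dropped_universe
    df.attrs["n_dropped_set"] = n_dropped_set
    return df


def write_ora_tsv(result: pd.DataFrame, path: str | Path) -> None:
    result.to_csv(path, sep="\t", index=False, float_format="%.6g")
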