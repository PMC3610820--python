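"""Coupling of cellular processes via dynamic protein-protein interactions.

Each network protein carries one or more functional categories (a reduced
GO-style annotation supplied as input).  For every unordered category pair
(A, B) — including A = A self-links — the number of network interactions
linking an A-annotated to a B-annotated protein is counted, along with how
many of them are dynamic.  Significance of dynamic enrichment per pair
comes from randomized networks in which the dynamic/non-dynamic edge
labels are redistributed uniformly over all edges, preserving the total
dynamic count: ``p_perm`` is the fraction of random networks showing a
strictly larger dynamic count for that pair, and a pair is *displayed*
when no more than ``display_rule`` of the random networks beat it
(the 10-of-1000 convention).

A per-category node enrichment (hypergeometric test of genes with at least
one dynamic interaction, Benjamini-Hochberg corrected) complements the
edge-level test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import InteractionNetwork

__all__ = [
    "annotation_map",
    "count_category_links",
    "permutation_process_test",
    "category_node_enrichment",
]


def annotation_map(annotation: pd.DataFrame) -> dict[str, set[str]]:
    """gene -> set of category ids from an annotation table."""
    if len(annotation) == 0:
        raise ValueError("annotation table is empty")
    out: dict[str, set[str]] = {}
    for g, c in zip(annotation["gene"].astype(str), annotation["category_id"].astype(str)):
        out.setdefault(g, set()).add(c)
    return out


def _edge_pairs(cats_a: set[str], cats_b: set[str]) -> set[tuple[str, str]]:
    """Category pairs an edge with endpoint annotations A, B contributes to.

    One endpoint must carry the first category and the other the second;
    multi-annotated endpoints contribute to every qualifying pair, each
    pair counted once per edge.
    """
    pairs = set()
    for a in cats_a:
        for b in cats_b:
            pairs.add((a, b) if a <= b else (b, a))
    return pairs


def count_category_links(
    net: InteractionNetwork,
    dynamic_edges,
    annotation: pd.DataFrame | dict,
) -> pd.DataFrame:
    """Interaction and dynamic-interaction counts per category pair.

    ``dynamic_edges`` is any iterable of (id_a, id_b) pairs (or a DataFrame
    with a ``dynamic`` column, from which the dynamic rows are taken).
    Returns every category pair with at least one linking edge, plus
    all-zero rows for annotated pairs without edges are omitted.
    """
    ann = annotation if isinstance(annotation, dict) else annotation_map(annotation)
    dyn = _dynamic_edge_set(dynamic_edges)
    n_int: dict[tuple[str, str], int] = {}
    n_dyn: dict[tuple[str, str], int] = {}
    for u, v in net.edges():
        cu, cv = ann.get(u), ann.get(v)
        if not cu or not cv:
            continue
        is_dyn = tuple(sorted((u, v))) in dyn
        for pair in _edge_pairs(cu, cv):
            n_int[pair] = n_int.get(pair, 0) + 1
            if is_dyn:
                n_dyn[pair] = n_dyn.get(pair, 0) + 1
    rows = [
        {
            "category_a": a,
            "category_b": b,
            "n_interactions": n_int[(a, b)],
            "n_dynamic": n_dyn.get((a, b), 0),
        }
        for (a, b) in sorted(n_int)
    ]
    return pd.DataFrame(
        rows, columns=["category_a", "category_b", "n_interactions", "n_dynamic"]
    )


def _dynamic_edge_set(dynamic_edges) -> set[tuple[str, str]]:
    if isinstance(dynamic_edges, pd.DataFrame):
        df = dynamic_edges
        if "dynamic" in df.columns:
            df = df[df["dynamic"].astype(bool)]
        return {tuple(sorted((str(a), str(b)))) for a, b in zip(df["id_a"], df["id_b"])}
    return {tuple(sorted((str(a), str(b)))) for a, b in dynamic_edges}


def permutation_process_test(
    net: InteractionNetwork,
    dynamic_edges,
    annotation: pd.DataFrame | dict,
    n_networks: int = 1000,
    seed: int | np.random.Generator | None = None,
    display_rule: int = 10,
) -> pd.DataFrame:
    """Randomization test for dynamic enrichment of category pairs.

    Each of the ``n_networks`` random networks keeps the graph and the
    annotation fixed and redistributes the dynamic labels uniformly over
    all edges (global dynamic count preserved).  ``p_perm`` is the fraction
    of random networks whose dynamic count for the pair strictly exceeds
    the observed one; ``displayed`` marks pairs with
    ``p_perm <= display_rule / n_networks``.
    """
    if n_networks < 100:
        raise ValueError("need at least 100 random networks")
    ann = annotation if isinstance(annotation, dict) else annotation_map(annotation)
    rng = np.random.default_rng(seed)
    dyn = _dynamic_edge_set(dynamic_edges)
    edges = net.edges()
    n_edges = len(edges)
    k = sum(1 for e in edges if e in dyn)

    observed = count_category_links(net, dynamic_edges, ann)
    pair_index = {
        (a, b): i
        for i, (a, b) in enumerate(zip(observed["category_a"], observed["category_b"]))
    }
    # edge x pair incidence (annotated edges only)
    incidence = np.zeros((n_edges, len(pair_index)))
    for e_i, (u, v) in enumerate(edges):
        cu, cv = ann.get(u), ann.get(v)
        if not cu or not cv:
            continue
        for pair in _edge_pairs(cu, cv):
            incidence[e_i, pair_index[pair]] = 1.0

    obs_counts = observed["n_dynamic"].to_numpy(dtype=float)
    if k == 0:
        p_perm = np.ones(len(pair_index))
    else:
        exceed = np.zeros(len(pair_index))
        labels = np.zeros(n_edges)
        labels[:k] = 1.0
        for _ in range(n_networks):
            rng.shuffle(labels)
            exceed += (labels @ incidence) > obs_counts
        p_perm = exceed / n_networks
    out = observed.copy()
    out["p_perm"] = p_perm
    out["displayed"] = p_perm <= display_rule / n_networks
    return out


@dataclass(frozen=True)
class CategoryEnrichment:
    category: str
    size: int
    n_dynamic_genes: int
    p: float
    fdr: float


def category_node_enrichment(
    annotation: pd.DataFrame | dict,
    dynamic_degrees: pd.Series,
) -> pd.DataFrame:
    """Hypergeometric enrichment of dynamically interacting genes.

    For each category: draw ``size`` genes (the category) from the
    ``N`` annotated genes of which ``n`` carry at least one dynamic
    interaction; the p-value is the upper tail of observing the category's
    dynamic-gene count.  Benjamini-Hochberg FDR across categories.
    Genes absent from ``dynamic_degrees`` count as non-dynamic.
    """
    ann = annotation if isinstance(annotation, dict) else annotation_map(annotation)
    genes = sorted(ann)
    dyn_gene = {
        g for g in genes if g in dynamic_degrees.index and dynamic_degrees[g] >= 1
    }
    big_n = len(genes)
    n_dyn = len(dyn_gene)
    cats: dict[str, set[str]] = {}
    for g, cset in ann.items():
        for c in cset:
            cats.setdefault(c, set()).add(g)
    rows = []
    for c in sorted(cats):
        members = cats[c]
        if len(members) == 0:
            raise ValueError(f"category {c} is empty")
        k = len(members & dyn_gene)
        p = float(stats.hypergeom.sf(k - 1, big_n, n_dyn, len(members)))
        rows.append(
            {"category": c, "size": len(members), "n_dynamic_genes": k, "p": p}
        )
    df = pd.DataFrame(rows, columns=["category", "size", "n_dynamic_genes", "p"])
    df["fdr"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
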