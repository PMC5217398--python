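"""Hypergeometric GO-term over-representation against a gene background.

For a term annotating M of the N background genes, with a DE set of n genes
of which m carry the term, the enrichment p-value is the upper hypergeometric
tail

    p = sum_{i=m}^{min(M, n)} C(M, i) * C(N-M, n-i) / C(N, n),

i.e. the chance of drawing at least m term genes when sampling n genes
without replacement from the background.  Terms are declared enriched under
the dual threshold p < 0.01 and BH FDR < 0.05, with the FDR family formed
within each GO namespace.  The background universe is the full tag-mapped
reference gene set by default.

Annotations are taken as given (no GO-graph ancestor closure); an optional
:func:`propagate_annotations` pre-processing step closes them over a
supplied term-parent table.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationMap",
    "load_annotation_tsv",
    "propagate_annotations",
    "hypergeom_upper_tail",
    "enrich",
]

#: gene id -> set of GO term ids
AnnotationMap = Mapping[str, set]


def load_annotation_tsv(path) -> dict[str, set[str]]:
    """Load a 2-column (gene, GO term) TSV into a gene -> terms map."""
    annotation: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            if gene == "gene" and term.lower().startswith("term"):
                continue  # header
            annotation.setdefault(gene, set()).add(term)
    return annotation


def load_term_parents_tsv(path) -> dict[str, set[str]]:
    """Load a 2-column (term, parent term) TSV (OBO-derived is_a edges)."""
    parents: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            child, parent = line.split("\t")[:2]
            parents.setdefault(child, set()).add(parent)
    return parents


def propagate_annotations(
    annotation: AnnotationMap, parents: Mapping[str, set]
) -> dict[str, set[str]]:
    """Close each gene's annotation over the term-parent relation (transitive)."""
    closure_cache: dict[str, frozenset[str]] = {}

    def closure(term: str) -> frozenset[str]:
        if term in closure_cache:
            return closure_cache[term]
        closure_cache[term] = frozenset()  # break cycles defensively
        acc = {term}
        for parent in parents.get(term, ()):
            acc |= closure(parent)
        result = frozenset(acc)
        closure_cache[term] = result
        return result

    return {
        gene: set().union(*(closure(t) for t in terms)) if terms else set()
        for gene, terms in annotation.items()
    }


def hypergeom_upper_tail(m: int, N: int, M: int, n: int, exact: bool = False):
    """P(X >= m) for X ~ Hypergeom(N population, M marked, n drawn).

    With ``exact=True`` the tail is summed in rational arithmetic
    (:class:`fractions.Fraction`), so identities such as
    upper(m) + lower(m-1) = 1 hold exactly; intended for small instances.
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError("require 0 <= M <= N and 0 <= n <= N")
    if m < 0:
        raise ValueError("m must be >= 0")
    if exact:
        denom = comb(N, n)
        total = sum(
            Fraction(comb(M, i) * comb(N - M, n - i), denom)
            for i in range(m, min(M, n) + 1)
        )
        return total if total else Fraction(0)
    return float(hypergeom.sf(m - 1, N, M, n))


def enrich(
    deg_set: set,
    annotation: AnnotationMap,
    universe: set,
    term_namespaces: Mapping[str, str] | None = None,
    p_threshold: float = 0.01,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of every annotated term in a DE set.

    ``universe`` is the background gene set (typically all tag-mapped
    reference genes); ``deg_set`` must be contained in it.  Annotations of
    genes outside the universe are ignored.  BH adjustment runs within each
    namespace when ``term_namespaces`` is given, otherwise over all tested
    terms.  Rows are sorted by p-value.
    """
    if not universe:
        raise ValueError("empty background universe")
    stray = set(deg_set) - set(universe)
    if stray:
        raise ValueError(f"DE genes outside the universe: {sorted(stray)[:5]}")
    N = len(universe)
    n = len(deg_set)
    term_genes: dict[str, set] = {}
    for gene in universe:
        for term in annotation.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        M = len(genes)
        m = len(genes & deg_set)
        p = hypergeom_upper_tail(m, N, M, n)
        rows.append(
            {
                "term": term,
                "namespace": (term_namespaces or {}).get(term, "all"),
                "n_universe": N,
                "n_term": M,
                "n_set": n,
                "n_hit": m,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["term", "namespace", "n_universe", "n_term", "n_set", "n_hit", "p_value"],
    )
    if len(out):
        out["fdr"] = 1.0
        for _, idx in out.groupby("namespace").groups.items():
            out.loc[idx, "fdr"] = multipletests(out.loc[idx, "p_value"], method="fdr_bh")[1]
        out["enriched"] = (out["p_value"] < p_threshold) & (out["fdr"] < fdr_threshold)
        out = out.sort_values(["p_value", "term"], ignore_index=True)
    else:
        out["fdr"] = []
        out["enriched"] = []
    return out
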