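"""Hypergeometric term-enrichment testing over an annotation hierarchy.

Annotations are propagated to all ancestor terms ("gene-to-all" mapping), and
over/under-representation of each term in a selected gene list is tested with
the hypergeometric distribution.  The conditional procedure walks the term
graph leaves-first and, before testing a parent, removes the genes already
explained by significant descendants — so a parent is only called when it
adds signal beyond its children.  Raw p-values are reported (ranked
ascending); no multiple-testing correction is applied to enrichment p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class Universe:
    """Gene universe with ancestor-propagated annotations."""

    gene_to_terms: dict[str, set]
    term_to_genes: dict[str, set]

    @property
    def n_genes(self) -> int:
        return len(self.gene_to_terms)

    @property
    def n_terms(self) -> int:
        return len(self.term_to_genes)


def read_ontology_tsv(path) -> nx.DiGraph:
    """child<TAB>parent edge list -> parent->child DiGraph."""
    df = pd.read_csv(path, sep="\t")
    dag = nx.DiGraph()
    for row in df.itertuples(index=False):
        dag.add_edge(row.parent, row.child)
    _check_acyclic(dag)
    return dag


def read_obo(path) -> nx.DiGraph:
    """Minimal OBO reader: [Term] stanzas with id/is_a lines only."""
    dag = nx.DiGraph()
    term = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                term = None
            elif line.startswith("id:") and term is None:
                term = line.split("id:", 1)[1].strip()
                dag.add_node(term)
            elif line.startswith("is_a:") and term is not None:
                parent = line.split("is_a:", 1)[1].strip().split("!")[0].strip()
                dag.add_edge(parent, term)
    _check_acyclic(dag)
    return dag


def _check_acyclic(dag: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"term graph contains a cycle: {cycle}")


def build_universe(annotations: pd.DataFrame, ontology: nx.DiGraph) -> Universe:
    """Propagate gene annotations to all ancestor terms and invert the map.

    ``annotations`` needs columns ``gene`` and ``term``; every annotated term
    must exist in the ontology.
    """
    _check_acyclic(ontology)
    unknown = set(annotations["term"]) - set(ontology.nodes)
    if unknown:
        raise ValueError(f"annotated terms absent from ontology: {sorted(unknown)[:10]}")
    ancestors = {t: nx.ancestors(ontology, t) | {t} for t in set(annotations["term"])}
    gene_to_terms: dict[str, set] = {}
    for row in annotations.itertuples(index=False):
        gene_to_terms.setdefault(row.gene, set()).update(ancestors[row.term])
    term_to_genes: dict[str, set] = {}
    for g, terms in gene_to_terms.items():
        for t in terms:
            term_to_genes.setdefault(t, set()).add(g)
    return Universe(gene_to_terms=gene_to_terms, term_to_genes=term_to_genes)


def hypergeom_term_test(
    selected_genes: set, universe: Universe, term: str, direction: str = "over"
) -> float:
    """P(X >= x) (over) or P(X <= x) (under) for the term's overlap with the
    selected genes, X ~ Hypergeom(N = universe genes, K = term size,
    n = selected size)."""
    if term not in universe.term_to_genes:
        raise KeyError(f"term {term!r} not in universe")
    selected = set(selected_genes)
    stray = selected - set(universe.gene_to_terms)
    if stray:
        raise ValueError(f"selected genes outside universe: {sorted(stray)[:10]}")
    return _hypergeom_p(
        n_universe=universe.n_genes,
        term_genes=universe.term_to_genes[term],
        selected=selected,
        direction=direction,
    )


def _hypergeom_p(n_universe: int, term_genes: set, selected: set, direction: str) -> float:
    x = len(term_genes & selected)
    big_k = len(term_genes)
    n = len(selected)
    if direction == "over":
        return float(hypergeom.sf(x - 1, n_universe, big_k, n))
    if direction == "under":
        return float(hypergeom.cdf(x, n_universe, big_k, n))
    raise ValueError("direction must be 'over' or 'under'")


def conditional_enrichment(
    selected: set,
    universe: Universe,
    ontology: nx.DiGraph,
    alpha: float = 0.05,
    direction: str = "over",
) -> pd.DataFrame:
    """Leaf-first conditional hypergeometric enrichment over all annotated terms.

    Terms are processed in reverse topological order (children before
    parents, same-depth ties by term ID); when a term is tested, genes
    belonging to its descendants already significant at ``alpha`` are removed
    from its gene set (the universe itself is unchanged).  Output rows:
    term, p_value, actual_count, expected_count, term_size, direction,
    conditioned; sorted by p ascending.
    """
    _check_acyclic(ontology)
    if not universe.term_to_genes:
        raise ValueError("empty universe: no annotated terms to test")
    selected = set(selected)
    stray = selected - set(universe.gene_to_terms)
    if stray:
        raise ValueError(f"selected genes outside universe: {sorted(stray)[:10]}")

    testable = [t for t in ontology.nodes if t in universe.term_to_genes]
    order = list(nx.lexicographical_topological_sort(ontology.subgraph(testable)))[::-1]
    n_univ = universe.n_genes
    n_sel = len(selected)
    significant: set[str] = set()
    rows = []
    for term in order:
        term_genes = set(universe.term_to_genes[term])
        sig_desc = [d for d in nx.descendants(ontology, term) if d in significant]
        eliminated = set()
        for d in sig_desc:
            eliminated |= universe.term_to_genes.get(d, set())
        test_genes = term_genes - eliminated
        x = len(test_genes & selected)
        if len(test_genes) == 0:
            p = 1.0
        else:
            p = _hypergeom_p(n_univ, test_genes, selected, direction)
        expected = n_sel * len(test_genes) / n_univ if n_univ else float("nan")
        rows.append(
            {
                "term": term,
                "p_value": p,
                "actual_count": x,
                "expected_count": expected,
                "term_size": len(test_genes),
                "direction": direction,
                "conditioned": bool(sig_desc),
            }
        )
        if p <= alpha:
            significant.add(term)
    out = pd.DataFrame(rows).sort_values(["p_value", "term"]).reset_index(drop=True)
    return out
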