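"""Classic and conditional Fisher enrichment over a term DAG.

Classic enrichment tests each term's annotated gene set against a module
with a one-sided Fisher exact (hypergeometric upper-tail) test, after
pruning terms with fewer than ``min_term_size`` annotated background genes.
Conditional enrichment walks the DAG leaves-to-root: when a child term has
already tested significant, its genes are removed from the parent's set
before the parent is tested, so a parent is only called enriched for signal
its children do not already explain.  Leaf terms' conditional p-values
therefore equal their classic ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import TopologicalSorter

import pandas as pd
from scipy import stats

__all__ = [
    "TermAnnotation",
    "load_annotation",
    "fisher_enrichment",
    "conditional_enrichment",
]


@dataclass
class TermAnnotation:
    """Term -> gene sets plus a rooted, acyclic parent structure.

    The true-path rule (child genes are a subset of parent genes) is
    enforced at construction by propagating annotations upward.
    """

    terms: dict[str, set]
    parents: dict[str, set]
    namespace: str = "synthetic"
    children: dict[str, set] = field(init=False)

    def __post_init__(self) -> None:
        self.terms = {t: set(g) for t, g in self.terms.items()}
        self.parents = {t: set(self.parents.get(t, set())) for t in self.terms}
        unknown = {p for ps in self.parents.values() for p in ps} - set(self.terms)
        if unknown:
            raise ValueError(f"parent terms without annotation: {sorted(unknown)[:5]}")
        self.children = {t: set() for t in self.terms}
        for t, ps in self.parents.items():
            for p in ps:
                self.children[p].add(t)
        # child-before-parent order; raises CycleError on a cyclic structure
        order = self.reverse_topological()
        for t in order:  # propagate upward: true-path rule
            for p in self.parents[t]:
                self.terms[p] |= self.terms[t]

    def reverse_topological(self) -> list[str]:
        """Children before parents, ties broken by term ID."""
        ts = TopologicalSorter()
        for t in sorted(self.terms):
            ts.add(t, *sorted(self.children[t]))
        return list(ts.static_order())

    @property
    def leaves(self) -> set:
        return {t for t, ch in self.children.items() if not ch}


def load_annotation(
    gmt_path, edges_path, namespace: str = "synthetic"
) -> TermAnnotation:
    """Read a GMT-style term/gene TSV plus a (child, parent) edge-list TSV."""
    terms: dict[str, set] = {}
    with open(gmt_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            # GMT column 2 is a description slot
            terms[parts[0]] = set(g for g in parts[2:] if g)
    parents: dict[str, set] = {t: set() for t in terms}
    edges = pd.read_csv(edges_path, sep="\t")
    for _, row in edges.iterrows():
        parents.setdefault(row["child"], set()).add(row["parent"])
    return TermAnnotation(terms, parents, namespace)


def _fisher_upper(k: int, K: int, n: int, N: int) -> float:
    """One-sided enrichment p: P(X >= k), X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    module_genes: set,
    background: set,
    annotation: TermAnnotation,
    min_term_size: int = 30,
) -> pd.DataFrame:
    """Classic one-sided Fisher enrichment per term.

    Terms with fewer than ``min_term_size`` annotated background genes are
    pruned from the hierarchy before testing.
    """
    if not set(module_genes):
        raise ValueError("empty module gene set")
    if not set(module_genes) <= set(background):
        raise ValueError("module genes must be a subset of the background")
    module = set(module_genes)
    N, n = len(set(background)), len(module)
    rows = []
    for term in sorted(annotation.terms):
        annotated = annotation.terms[term] & set(background)
        K = len(annotated)
        if K < min_term_size:
            continue
        k = len(annotated & module)
        rows.append(
            {"term": term, "k": k, "K": K, "n": n, "N": N,
             "p_classic": _fisher_upper(k, K, n, N),
             "effective_gene_set_size": K}
        )
    return pd.DataFrame(rows)


def conditional_enrichment(
    module_genes: set,
    background: set,
    annotation: TermAnnotation,
    sig_threshold: float = 0.05,
    min_term_size: int = 30,
) -> pd.DataFrame:
    """Child-gene-removal enrichment, recursing from the leaves to the root.

    Each term is tested on its gene set minus the union of the genes of its
    significant children (child conditional p < ``sig_threshold``), judged
    recursively in reverse topological order.  Terms pruned by
    ``min_term_size`` are neither tested nor treated as significant
    children.
    """
    classic = fisher_enrichment(module_genes, background, annotation, min_term_size)
    if classic.empty:
        return classic.assign(p_conditional=pd.Series(dtype=float))
    module = set(module_genes) & set(background)
    bg = set(background)
    N, n = len(bg), len(module)
    kept = set(classic["term"])
    p_cond: dict[str, float] = {}
    eff_size: dict[str, int] = {}
    for term in annotation.reverse_topological():
        if term not in kept:
            continue
        removed: set = set()
        for ch in sorted(annotation.children[term]):
            if ch in p_cond and p_cond[ch] < sig_threshold:
                removed |= annotation.terms[ch] & bg
        effective = (annotation.terms[term] & bg) - removed
        K = len(effective)
        k = len(effective & module)
        p_cond[term] = _fisher_upper(k, K, n, N) if K > 0 else 1.0
        eff_size[term] = K
    out = classic.copy()
    out["p_conditional"] = out["term"].map(p_cond)
    out["effective_gene_set_size"] = out["term"].map(eff_size)
    return out
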