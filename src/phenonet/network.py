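"""Subsampling-robust similarity matrix and module extraction.

A single sparse canonical fit gives one weight vector per feature; the
robust adjacency repeats the fit over many random feature subsamples
(without replacement, typically 70% of mRNAs and 90% of miRNAs per round)
and averages |w_i * w_j| over the rounds in which features i and j were
co-sampled.  Because each weight vector has unit L2 norm, every entry lies
in [0, 1] and the matrix is symmetric with a zero diagonal by convention.
Modules are average-linkage hierarchical clusters of 1 - A; edge signs come
from the Pearson correlation of the two features' expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .smcca import SmccaParams, smcca_weights, standardize_columns

__all__ = [
    "SimilarityMatrix",
    "NetworkModule",
    "robust_adjacency",
    "detect_modules",
    "assign_edge_signs",
]

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    """Symmetric feature-similarity (adjacency) matrix over both omics blocks.

    Feature order is the mRNA block followed by the miRNA block;
    ``cosample_counts`` records how many subsampling rounds co-sampled each
    pair (entries never co-sampled are 0 in ``values``).
    """

    values: pd.DataFrame
    kinds: pd.Series  # feature -> "mRNA" | "miRNA"
    cosample_counts: pd.DataFrame

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class NetworkModule:
    module_id: int
    nodes: list[str]
    kinds: pd.Series
    adjacency: pd.DataFrame
    # rows of (source, target, weight, sign); sign filled by assign_edge_signs
    edges: pd.DataFrame = field(default=None)

    def edge_table(self) -> pd.DataFrame:
        if self.edges is not None:
            return self.edges
        rows = []
        a = self.adjacency
        for i, u in enumerate(self.nodes):
            for v in self.nodes[i + 1 :]:
                w = a.loc[u, v]
                if w > 0:
                    rows.append({"source": u, "target": v, "weight": float(w)})
        return pd.DataFrame(rows, columns=["source", "target", "weight"])


def robust_adjacency(
    X1: np.ndarray,
    X2: np.ndarray,
    Y: np.ndarray,
    params: SmccaParams,
    feature_ids_1: list[str],
    feature_ids_2: list[str],
    prop1: float = 0.7,
    prop2: float = 0.9,
    reps: int = 1000,
    seed: int = 0,
) -> SimilarityMatrix:
    """Average |w w'| over seeded feature-subsampling repetitions.

    Each repetition draws ceil(prop1*p1) mRNA and ceil(prop2*p2) miRNA
    features without replacement, fits the sparse canonical weights on the
    subset, and accumulates |w_i w_j| for all co-sampled pairs.  The final
    entry is the accumulated sum divided by the pair's co-sampling count,
    which avoids biasing rarely co-sampled pairs downward.
    """
    if not (0 < prop1 <= 1 and 0 < prop2 <= 1):
        raise ValueError("subsampling proportions must be in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    X1 = standardize_columns(X1)
    X2 = standardize_columns(X2)
    p1, p2 = X1.shape[1], X2.shape[1]
    p = p1 + p2
    rng = np.random.default_rng(seed)
    s1, s2 = int(np.ceil(prop1 * p1)), int(np.ceil(prop2 * p2))
    acc = np.zeros((p, p))
    cnt = np.zeros((p, p), dtype=np.int64)
    skipped = 0
    for _ in range(reps):
        i1 = np.sort(rng.choice(p1, size=s1, replace=False))
        i2 = np.sort(rng.choice(p2, size=s2, replace=False))
        if i1.size == 0 or i2.size == 0:
            skipped += 1
            continue
        fit = smcca_weights(X1[:, i1], X2[:, i2], Y, params)
        w = np.zeros(p)
        w[i1] = fit.w1
        w[p1 + i2] = fit.w2
        sel = np.concatenate([i1, p1 + i2])
        outer = np.abs(np.outer(w[sel], w[sel]))
        acc[np.ix_(sel, sel)] += outer
        cnt[np.ix_(sel, sel)] += 1
    if skipped:
        logger.warning("skipped %d repetitions with an empty block", skipped)
    with np.errstate(invalid="ignore"):
        A = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    np.fill_diagonal(A, 0.0)
    A = 0.5 * (A + A.T)
    ids = list(feature_ids_1) + list(feature_ids_2)
    kinds = pd.Series(
        ["mRNA"] * p1 + ["miRNA"] * p2, index=ids, name="kind"
    )
    return SimilarityMatrix(
        pd.DataFrame(A, index=ids, columns=ids),
        kinds,
        pd.DataFrame(cnt, index=ids, columns=ids),
    )


def detect_modules(
    sim: SimilarityMatrix,
    n_modules: int | None = None,
    cut_height: float | None = None,
    min_size: int = 5,
) -> list[NetworkModule]:
    """Average-linkage clustering of 1 - A, cut by count or height.

    Clusters smaller than ``min_size`` are dropped.  Returned modules are
    disjoint and ordered by decreasing size; ordering and membership are
    invariant to the input feature ordering.
    """
    if (n_modules is None) == (cut_height is None):
        raise ValueError("specify exactly one of n_modules or cut_height")
    # canonical feature order for permutation-invariant linkage
    order = np.argsort(np.asarray(sim.values.index))
    ids = np.asarray(sim.values.index)[order]
    A = sim.values.to_numpy()[np.ix_(order, order)]
    D = 1.0 - np.clip(A, 0.0, 1.0)
    np.fill_diagonal(D, 0.0)
    Z = average(squareform(D, checks=False))
    if n_modules is not None:
        labels = fcluster(Z, t=n_modules, criterion="maxclust")
    else:
        labels = fcluster(Z, t=cut_height, criterion="distance")
    modules = []
    for lab in np.unique(labels):
        members = sorted(ids[labels == lab])
        if len(members) < min_size:
            continue
        sub = sim.values.loc[members, members]
        modules.append(
            NetworkModule(0, members, sim.kinds.loc[members], sub)
        )
    if not modules:
        logger.warning("all clusters below min_size=%d; no modules", min_size)
    modules.sort(key=lambda m: (-len(m.nodes), m.nodes[0]))
    for i, m in enumerate(modules, start=1):
        m.module_id = i
    return modules


def assign_edge_signs(module: NetworkModule, expr: pd.DataFrame) -> NetworkModule:
    """Sign each module edge by the Pearson correlation of its endpoints.

    ``expr`` is a feature x sample expression matrix covering all module
    nodes.  An exactly zero correlation is assigned "+" and flagged.
    """
    missing = [n for n in module.nodes if n not in expr.index]
    if missing:
        raise KeyError(f"expression missing for nodes: {missing[:5]}")
    sub = expr.loc[module.nodes].to_numpy(dtype=float)
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        bad = [n for n, s in zip(module.nodes, sd) if s == 0]
        raise ValueError(f"constant expression for features: {bad[:5]}")
    corr = np.corrcoef(sub)
    edges = module.edge_table()[["source", "target", "weight"]].copy()
    pos = {n: i for i, n in enumerate(module.nodes)}
    r = np.array([corr[pos[s], pos[t]] for s, t in zip(edges["source"], edges["target"])])
    edges["sign"] = np.where(r < 0, "-", "+")
    edges["zero_correlation"] = r == 0
    edges["source_kind"] = module.kinds.loc[edges["source"]].to_numpy()
    edges["target_kind"] = module.kinds.loc[edges["target"]].to_numpy()
    module.edges = edges
    return module
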