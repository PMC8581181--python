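"""Edge-threshold pruning of network modules against a phenotype.

For each module the candidate thresholds run from 0.001 up to the maximum
off-diagonal adjacency entry in steps of 0.001.  At each threshold tau the
module keeps edges with weight >= tau and drops isolated nodes; the quality
of the trimmed network is the absolute Pearson correlation between the
phenotype and the first principal component of the surviving nodes'
(feature-standardized) expression.  The selected threshold maximizes |r|,
with ties broken toward the larger (sparser) threshold; the full
(threshold, size, |r|) curve is returned so node counts and miRNA:mRNA
balance can also be weighed by the analyst.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import NetworkModule

__all__ = [
    "PrunedNetwork",
    "threshold_grid",
    "network_pc1_correlation",
    "prune_module",
]


@dataclass
class PrunedNetwork:
    module_id: int
    threshold: float
    nodes: list[str]
    kinds: pd.Series
    edges: pd.DataFrame
    pc1_correlation: float
    p_value: float
    curve: pd.DataFrame

    @property
    def n_mirna(self) -> int:
        return int((self.kinds == "miRNA").sum())

    @property
    def n_mrna(self) -> int:
        return int((self.kinds == "mRNA").sum())


def threshold_grid(adjacency: pd.DataFrame, step: float = 0.001) -> np.ndarray:
    """{step, 2*step, ...} up to the largest multiple <= max off-diagonal A."""
    a = adjacency.to_numpy(dtype=float).copy()
    if a.size == 0:
        raise ValueError("empty module adjacency")
    np.fill_diagonal(a, 0.0)
    amax = float(a.max())
    n = int(np.floor(amax / step + 1e-9))
    if n < 1:
        warnings.warn(
            f"max adjacency {amax:.6f} below {step}; single-threshold grid"
        )
        return np.array([step])
    return np.arange(1, n + 1) * step


def network_pc1_correlation(
    nodes: list[str], expr: pd.DataFrame, y: pd.Series
) -> tuple[float, float]:
    """|Pearson r| between the phenotype and PC1 of the node expression.

    PC1 scores are the leading right singular vector of the
    feature-standardized node x sample submatrix; the two-sided p-value uses
    the t transform with n - 2 degrees of freedom.  The result is invariant
    to the arbitrary sign of the principal component.
    """
    if not nodes:
        raise ValueError("need at least one node")
    sub = expr.loc[nodes, y.index].to_numpy(dtype=float)
    n = sub.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mu) / sd
    if len(nodes) == 1:
        scores = z[0]
    else:
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        scores = vt[0]
    if np.std(scores) == 0:
        raise ValueError("constant PC1 scores")
    r = float(np.corrcoef(scores, y.to_numpy(dtype=float))[0, 1])
    r_abs = min(abs(r), 1.0)
    if r_abs >= 1.0:
        return 1.0, 0.0
    t = r_abs * np.sqrt((n - 2) / (1.0 - r_abs**2))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    return r_abs, float(p)


def prune_module(
    module: NetworkModule,
    expr: pd.DataFrame,
    y: pd.Series,
    step: float = 0.001,
) -> PrunedNetwork:
    """Scan the threshold grid and keep the trimming that maximizes |r|.

    Thresholds whose trimmed network is empty are recorded in the curve but
    excluded from the argmax; ties prefer the larger threshold.  Node and
    edge counts are non-increasing in tau by construction.
    """
    edges = module.edge_table()
    if edges.empty:
        raise ValueError(f"module {module.module_id} has no edges")
    grid = threshold_grid(module.adjacency, step=step)
    rows = []
    best = None
    for tau in grid:
        kept = edges[edges["weight"] >= tau - 1e-12]
        nodes = sorted(set(kept["source"]) | set(kept["target"]))
        if not nodes:
            rows.append(
                {"threshold": tau, "n_nodes": 0, "n_mirna": 0, "n_mrna": 0,
                 "n_edges": 0, "abs_cor": np.nan, "p_value": np.nan}
            )
            continue
        kinds = module.kinds.loc[nodes]
        r, p = network_pc1_correlation(nodes, expr, y)
        rows.append(
            {"threshold": tau, "n_nodes": len(nodes),
             "n_mirna": int((kinds == "miRNA").sum()),
             "n_mrna": int((kinds == "mRNA").sum()),
             "n_edges": len(kept), "abs_cor": r, "p_value": p}
        )
        # >= so later (larger) thresholds win ties
        if best is None or r >= best[1] - 1e-15:
            best = (tau, r, p, nodes, kinds, kept)
    curve = pd.DataFrame(rows)
    if best is None:
        raise ValueError("every threshold yields an empty network")
    tau, r, p, nodes, kinds, kept = best
    return PrunedNetwork(
        module.module_id, float(tau), nodes, kinds,
        kept.reset_index(drop=True), r, p, curve,
    )
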