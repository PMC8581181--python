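"""Network quality assessment, single-omics comparison, and cohort summaries.

Quality of a discovered miRNA-mRNA network is judged without ground truth
by (i) the fraction of its negatively correlated miRNA-mRNA pairs found in
an offline target database (predicted or experimentally validated evidence)
and (ii) the fraction of its miRNA nodes appearing in a curated list of
phenotype-associated miRNAs, where list entries lacking a 3p/5p arm suffix
match both mature arms.  The single-omics comparison runs per-feature
Pearson tests with Benjamini-Hochberg correction, the classical baseline
that network discovery is meant to complement.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .prune import PrunedNetwork

__all__ = [
    "rate_percent",
    "load_target_db",
    "pair_validation_rate",
    "published_mirna_rate",
    "single_omics_correlations",
    "network_vs_single_overlap",
    "correlation_range_summary",
    "classify_spirometry",
    "cohort_summary",
]

logger = logging.getLogger(__name__)


def rate_percent(n_found: int, n_total: int) -> float | None:
    """Percentage n_found/n_total on the 0-100 scale; None when undefined."""
    if n_total <= 0:
        return None
    return 100.0 * n_found / n_total


def load_target_db(path_or_df) -> pd.DataFrame:
    """Load an offline (mirna, gene, evidence, source) table, deduplicated."""
    db = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df, sep="\t")
    )
    required = {"mirna", "gene", "evidence"}
    if not required <= set(db.columns):
        raise ValueError(f"target DB needs columns {sorted(required)}")
    bad = set(db["evidence"].unique()) - {"predicted", "validated"}
    if bad:
        raise ValueError(f"unknown evidence labels: {sorted(bad)}")
    return db.drop_duplicates(subset=["mirna", "gene", "evidence"]).reset_index(
        drop=True
    )


def _negative_pairs(
    networks: list[PrunedNetwork], expr: pd.DataFrame
) -> set[tuple[str, str]]:
    """Deduplicated miRNA-mRNA edges with strictly negative expression correlation."""
    pairs: set[tuple[str, str]] = set()
    for net in networks:
        e = net.edges
        cross = e[e["source_kind"] != e["target_kind"]]
        for _, row in cross.iterrows():
            if row["source_kind"] == "miRNA":
                mi, g = row["source"], row["target"]
            else:
                mi, g = row["target"], row["source"]
            r = np.corrcoef(
                expr.loc[mi].to_numpy(dtype=float),
                expr.loc[g].to_numpy(dtype=float),
            )[0, 1]
            if r < 0:  # exactly zero counts as non-negative
                pairs.add((mi, g))
    return pairs


def pair_validation_rate(
    networks: list[PrunedNetwork],
    expr: pd.DataFrame,
    db: pd.DataFrame,
    evidence: str = "predicted",
) -> tuple[int, int, float | None]:
    """(n_pairs, n_found, rate%) of negative miRNA-mRNA pairs present in the DB."""
    if evidence not in {"predicted", "validated"}:
        raise ValueError("evidence must be 'predicted' or 'validated'")
    pairs = _negative_pairs(networks, expr)
    if not pairs:
        return 0, 0, None
    ref = set(
        zip(db.loc[db["evidence"] == evidence, "mirna"],
            db.loc[db["evidence"] == evidence, "gene"])
    )
    found = len(pairs & ref)
    return len(pairs), found, rate_percent(found, len(pairs))


def expand_arms(names: list[str]) -> set[str]:
    """Expand arm-less miRNA names to both -3p and -5p mature forms."""
    out: set[str] = set()
    for name in names:
        if name.endswith(("-3p", "-5p")):
            out.add(name)
        else:
            out.update({f"{name}-3p", f"{name}-5p"})
    return out


def published_mirna_rate(
    networks: list[PrunedNetwork],
    published: list[str],
    arm_expansion: bool = True,
) -> tuple[int, int, float | None]:
    """(n_mirna, n_matched, rate%) of network miRNAs found in a published list."""
    nodes: set[str] = set()
    for net in networks:
        nodes.update(n for n, k in net.kinds.items() if k == "miRNA")
    if not nodes:
        return 0, 0, None
    ref = expand_arms(published) if arm_expansion else set(published)
    matched = len(nodes & ref)
    return len(nodes), matched, rate_percent(matched, len(nodes))


def single_omics_correlations(
    expr: pd.DataFrame, y: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature Pearson correlation with BH-adjusted two-sided p-values."""
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples")
    x = expr.loc[:, y.index].to_numpy(dtype=float)
    yy = y.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.info("excluding %d constant features from testing", constant.sum())
    xc = x - x.mean(axis=1, keepdims=True)
    yc = yy - yy.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    out = pd.DataFrame(
        {"feature": expr.index, "r": r, "p": p}
    )
    out.loc[constant, ["r", "p"]] = np.nan
    ok = ~constant
    p_adj = np.full(len(out), np.nan)
    if ok.any():
        p_adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    out["p_adj"] = p_adj
    out["significant"] = out["p_adj"] < alpha
    return out


def network_vs_single_overlap(
    networks: list[PrunedNetwork], single_table: pd.DataFrame
) -> pd.DataFrame:
    """Per omic kind, how many network nodes the single-feature tests flagged."""
    sig = set(single_table.loc[single_table["significant"].fillna(False), "feature"])
    rows = []
    for kind in ("mRNA", "miRNA"):
        nodes: set[str] = set()
        for net in networks:
            nodes.update(n for n, k in net.kinds.items() if k == kind)
        rows.append(
            {
                "kind": kind,
                "n_nodes": len(nodes),
                "n_single_significant": len(nodes & sig),
                "n_network_only": len(nodes - sig),
            }
        )
    return pd.DataFrame(rows)


def correlation_range_summary(
    X1: pd.DataFrame, X2: pd.DataFrame, y: pd.Series
) -> pd.DataFrame:
    """Five-number summaries of all pairwise Pearson correlations by pair type.

    ``X1``/``X2`` are feature x sample expression blocks.  Constant features
    are excluded (their count is reported in the ``n_excluded`` column).
    """
    def _rows(block: pd.DataFrame) -> tuple[np.ndarray, int]:
        x = block.to_numpy(dtype=float)
        keep = x.std(axis=1, ddof=1) > 0
        return x[keep], int((~keep).sum())

    a1, ex1 = _rows(X1)
    a2, ex2 = _rows(X2)
    yy = y.to_numpy(dtype=float)

    def _summary(vals: np.ndarray, name: str, n_excl: int) -> dict:
        if vals.size == 0:
            return {"pair_type": name, "n_pairs": 0, "n_excluded": n_excl,
                    "min": np.nan, "q1": np.nan, "median": np.nan,
                    "q3": np.nan, "max": np.nan}
        q = np.percentile(vals, [0, 25, 50, 75, 100])
        return {"pair_type": name, "n_pairs": int(vals.size),
                "n_excluded": n_excl, "min": q[0], "q1": q[1],
                "median": q[2], "q3": q[3], "max": q[4]}

    def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        if a.size == 0 or b.size == 0:
            return np.array([])
        za = (a - a.mean(1, keepdims=True)) / a.std(1, ddof=1, keepdims=True)
        zb = (b - b.mean(1, keepdims=True)) / b.std(1, ddof=1, keepdims=True)
        return (za @ zb.T).ravel() / (a.shape[1] - 1)

    yv = yy[None, :]
    return pd.DataFrame(
        [
            _summary(_cross(a1, a2), "mRNA-miRNA", ex1 + ex2),
            _summary(_cross(a1, yv), "mRNA-phenotype", ex1),
            _summary(_cross(a2, yv), "miRNA-phenotype", ex2),
        ]
    )


def classify_spirometry(fev1pp: float, ratio: float) -> str:
    """Spirometric class from FEV1 percent-predicted and the FEV1/FVC ratio.

    Obstructed subjects (ratio < 0.7) are graded GOLD 1-4 by FEV1pp cutpoints
    80/50/30; preserved-ratio subjects are ``normal`` at FEV1pp >= 80 and
    ``PRISm`` below.
    """
    if fev1pp < 0 or not 0 <= ratio <= 1:
        raise ValueError("fev1pp must be >= 0 and ratio in [0, 1]")
    if ratio < 0.7:
        if fev1pp >= 80:
            return "GOLD1"
        if fev1pp >= 50:
            return "GOLD2"
        if fev1pp >= 30:
            return "GOLD3"
        return "GOLD4"
    return "normal" if fev1pp >= 80 else "PRISm"


def cohort_summary(
    covariates: pd.DataFrame,
    phenotypes: pd.DataFrame,
    groups: pd.Series,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group descriptive table with between-group comparison p-values.

    Categorical variables get ``count (percent)`` cells with a chi-square
    test (no continuity correction); continuous variables get ``mean (SD)``
    cells with one-way ANOVA.  Percentages are rounded to 1 decimal and SDs
    to 2, the conventional presentation.
    """
    data = pd.concat([covariates, phenotypes], axis=1)
    groups = groups.loc[data.index]
    levels = sorted(groups.unique())
    if categorical is None:
        categorical = [
            c for c in data.columns
            if data[c].dtype == object or data[c].nunique() <= 2
        ]
    rows = []
    for var in data.columns:
        cells = {}
        if var in categorical:
            tab = pd.crosstab(data[var], groups)
            for g in levels:
                n_g = int((groups == g).sum())
                # report the top (sorted-last) category, e.g. 1 for binaries
                cat = sorted(data[var].unique())[-1]
                cnt = int(tab.loc[cat, g]) if cat in tab.index else 0
                cells[str(g)] = f"{cnt} ({round(100.0 * cnt / n_g, 1)})"
            if tab.shape[1] > 1 and tab.shape[0] > 1:
                _, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            else:
                p = np.nan
        else:
            for g in levels:
                vals = data.loc[groups == g, var].astype(float)
                sd = f"{vals.std(ddof=1):.2f}" if len(vals) > 1 else "NA"
                cells[str(g)] = f"{vals.mean():.2f} ({sd})"
            samples = [
                data.loc[groups == g, var].astype(float).to_numpy() for g in levels
            ]
            p = stats.f_oneway(*samples).pvalue if len(samples) > 1 else np.nan
        rows.append({"variable": var, **cells, "p_value": p})
    return pd.DataFrame(rows)
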