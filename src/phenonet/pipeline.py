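"""End-to-end orchestration: simulate -> preprocess -> adjust -> canonical
fit -> network -> prune -> evaluate -> enrich.

Every stage draws its randomness from a per-stage seed derived from the
single pipeline seed by a fixed counter offset, so stages can be re-run in
isolation and a fixed configuration reproduces every output table byte for
byte.  Stage boundaries log feature and sample counts so a run reads like
the analysis narrative (how many features each filter kept, how many
modules were found, and so on).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adjust import apply_regime
from .enrich import TermAnnotation, conditional_enrichment, fisher_enrichment
from .evaluate import (
    load_target_db,
    network_vs_single_overlap,
    pair_validation_rate,
    published_mirna_rate,
    single_omics_correlations,
)
from .network import assign_edge_signs, detect_modules, robust_adjacency
from .preprocess import (
    FilterParams,
    filter_features,
    remove_outlier_features,
    ruvr_correct,
    upper_quartile_normalize,
    vst,
)
from .prune import prune_module
from .smcca import SmccaParams, cv_grid_search, default_grid
from .synthetic import SimulationConfig, generate_cohort, generate_target_db

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets (single pipeline seed fans out deterministically)
_STAGE_OFFSETS = {"simulate": 0, "cv": 1, "subsample": 2, "fixtures": 3}


def stage_seed(seed: int, stage: str) -> int:
    return (int(seed) * 10_007 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    seed: int = 1
    out_dir: str = "results/run"
    simulation: SimulationConfig | None = None
    regime: str = "partial"
    # preprocessing (defaults sized for the synthetic cohort)
    mrna_filter: FilterParams = field(
        default_factory=lambda: FilterParams(5, 100, 2.0, None)
    )
    mirna_filter: FilterParams = field(
        default_factory=lambda: FilterParams(5, 100, 2.0, 5_000_000)
    )
    ruv_k: int = 1
    run_preprocess: bool = True
    run_cv: bool = False
    cv_folds: int = 4
    smcca: SmccaParams = field(default_factory=SmccaParams)
    prop1: float = 0.7
    prop2: float = 0.9
    reps: int = 100
    n_modules: int = 3
    cut_height: float | None = None
    min_module_size: int = 5
    prune_step: float = 0.001
    # evaluation fixtures
    target_db_decoys: int = 300
    target_db_frac_validated: float = 0.5
    enrich_min_term_size: int = 10
    enrich_sig_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in _FIELD_NAMES})
        if sim is not None:
            sim = {
                k: tuple(tuple(x) if isinstance(x, list) else x for x in v)
                if isinstance(v, list) else v
                for k, v in sim.items()
            }
            cfg.simulation = SimulationConfig(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_FIELD_NAMES = {f.name for f in dataclasses.fields(PipelineConfig)}


@dataclass
class ResultsBundle:
    config: PipelineConfig
    tables: dict
    manifest: dict
    truth: object = None
    networks: list = field(default_factory=list)
    expression: pd.DataFrame = None
    phenotype: pd.Series = None
    target_db: pd.DataFrame = None


def _write_tsv(path: Path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def preprocess_block(
    counts: pd.DataFrame,
    params: FilterParams,
    design: pd.DataFrame,
    ruv_k: int,
    ruv_columns: list[str],
    label: str,
) -> pd.DataFrame:
    """Outlier removal, expression filter, UQ normalization, residual-factor
    correction, and variance stabilization for one count matrix."""
    n0 = len(counts)
    if params.max_single_read is not None:
        counts = remove_outlier_features(counts, params.max_single_read)
    n1 = len(counts)
    counts = filter_features(counts, params)
    logger.info(
        "%s: %d features -> %d after outlier removal -> %d after filter",
        label, n0, n1, len(counts),
    )
    if counts.empty:
        raise RuntimeError(f"preprocess left no {label} features")
    norm = upper_quartile_normalize(counts)
    if ruv_k > 0:
        logn = np.log(norm + 0.5)
        corrected_log = ruvr_correct(logn, design, k=ruv_k, covariate_columns=ruv_columns)
        corrected = np.maximum(np.exp(corrected_log) - 0.5, 0.0)
    else:
        corrected = norm
    return vst(corrected)


def run_pipeline(config: PipelineConfig, write: bool = True) -> ResultsBundle:
    """Execute the full analysis; returns all stage tables and ground truth."""
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    # --- simulate ---------------------------------------------------------
    sim = config.simulation or SimulationConfig(
        seed=stage_seed(config.seed, "simulate")
    )
    try:
        mrna_counts, mirna_counts, cov, pheno, truth = generate_cohort(sim)
        logger.info(
            "simulated cohort: %d subjects, %d mRNA, %d miRNA",
            sim.n_subjects, sim.n_mrna, sim.n_mirna,
        )
    except Exception:
        logger.error("stage 'simulate' failed")
        raise

    # --- preprocess -------------------------------------------------------
    try:
        if config.run_preprocess:
            ruv_cols = ["sex", "race", "age", "smoking",
                        "wbc_neutrophil", "wbc_lymphocyte"]
            mrna_expr = preprocess_block(
                mrna_counts, config.mrna_filter, cov, config.ruv_k, ruv_cols, "mRNA"
            )
            mirna_expr = preprocess_block(
                mirna_counts, config.mirna_filter, cov, config.ruv_k, ruv_cols, "miRNA"
            )
        else:
            mrna_expr = mrna_counts.astype(float)
            mirna_expr = mirna_counts.astype(float)
    except Exception:
        logger.error("stage 'preprocess' failed")
        raise

    # --- covariate adjustment --------------------------------------------
    mrna_adj, mirna_adj, y = apply_regime(
        mrna_expr, mirna_expr, pheno, cov, config.regime
    )
    expr_all = pd.concat([mrna_adj, mirna_adj])

    # --- canonical parameters (optional CV) -------------------------------
    params = config.smcca
    X1 = mrna_adj.T.to_numpy()
    X2 = mirna_adj.T.to_numpy()
    if config.run_cv:
        cv = cv_grid_search(
            X1, X2, y.to_numpy(), default_grid(),
            folds=config.cv_folds, seed=stage_seed(config.seed, "cv"),
        )
        params = dataclasses.replace(
            config.smcca, a=cv.best.a, b=cv.best.b, c=cv.best.c,
            l1=cv.best.l1, l2=cv.best.l2,
        )
        tables["cv_grid"] = cv.table
        logger.info("CV selected a=%g b=%g c=%g l1=%g l2=%g",
                    params.a, params.b, params.c, params.l1, params.l2)

    # --- robust network ---------------------------------------------------
    sim_matrix = robust_adjacency(
        X1, X2, y.to_numpy(), params,
        list(mrna_adj.index), list(mirna_adj.index),
        prop1=config.prop1, prop2=config.prop2,
        reps=config.reps, seed=stage_seed(config.seed, "subsample"),
    )
    modules = detect_modules(
        sim_matrix, n_modules=config.n_modules, cut_height=config.cut_height,
        min_size=config.min_module_size,
    )
    logger.info("detected %d modules (sizes: %s)",
                len(modules), [len(m.nodes) for m in modules])
    for m in modules:
        assign_edge_signs(m, expr_all)

    # --- prune ------------------------------------------------------------
    networks = []
    module_rows = []
    for m in modules:
        try:
            net = prune_module(m, expr_all, y, step=config.prune_step)
        except ValueError as exc:
            logger.warning("module %d not prunable: %s", m.module_id, exc)
            continue
        networks.append(net)
        module_rows.append(
            {"module": m.module_id, "n_features": len(m.nodes),
             "threshold": net.threshold, "n_nodes": len(net.nodes),
             "n_mirna": net.n_mirna, "n_mrna": net.n_mrna,
             "abs_cor": net.pc1_correlation, "p_value": net.p_value}
        )
        tables[f"prune_curve_module{m.module_id}"] = net.curve
        tables[f"network_module{m.module_id}"] = net.edges
    tables["modules"] = pd.DataFrame(module_rows)
    networks.sort(key=lambda nw: -nw.pc1_correlation)

    # --- evaluate ---------------------------------------------------------
    fixture_seed = stage_seed(config.seed, "fixtures")
    db = load_target_db(
        generate_target_db(
            truth, extra_random_pairs=config.target_db_decoys,
            frac_validated=config.target_db_frac_validated, seed=fixture_seed,
        )
    )
    eval_rows = []
    for evidence in ("predicted", "validated"):
        n_pairs, n_found, rate = pair_validation_rate(
            networks, expr_all, db, evidence
        )
        eval_rows.append({"metric": f"{evidence}_pair_rate", "n": n_pairs,
                          "found": n_found, "rate_pct": rate})
    # synthetic miRNA IDs carry no 3p/5p arm suffix; match them literally
    published = sorted({m for m, _, _ in truth.planted_pairs})
    n_mi, n_match, rate = published_mirna_rate(networks, published, arm_expansion=False)
    eval_rows.append({"metric": "published_mirna_rate", "n": n_mi,
                      "found": n_match, "rate_pct": rate})
    tables["network_quality"] = pd.DataFrame(eval_rows)

    single = single_omics_correlations(expr_all, y)
    tables["single_omics"] = single
    tables["network_vs_single"] = network_vs_single_overlap(networks, single)

    # --- enrichment over a planted two-level term structure ----------------
    genes = list(mrna_adj.index)
    if networks and networks[0].n_mrna >= 2:
        top_genes = {n for n, k in networks[0].kinds.items() if k == "mRNA"}
        terms = {"T_root": set(genes)}
        parents: dict[str, set] = {"T_root": set()}
        for k in range(sim.n_modules):
            members = set(truth.module_features(k)) & set(genes)
            if members:
                terms[f"T_module{k}"] = members
                parents[f"T_module{k}"] = {"T_root"}
        ann = TermAnnotation(terms, parents)
        tables["enrichment"] = conditional_enrichment(
            top_genes, set(genes), ann,
            sig_threshold=config.enrich_sig_threshold,
            min_term_size=config.enrich_min_term_size,
        )

    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "tables": sorted(tables),
    }
    if write:
        for name, df in tables.items():
            _write_tsv(out / f"{name}.tsv", df)
        _write_tsv(out / "adjacency.tsv", sim_matrix.values, index=True)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return ResultsBundle(
        config, tables, manifest, truth=truth, networks=networks,
        expression=expr_all, phenotype=y, target_db=db,
    )


def planted_recovery_f1(nodes, truth) -> float:
    """F1 of a node set against the union of planted module members.

    Both planted modules carry a phenotype effect, so a single canonical
    direction legitimately spans them; recovery is therefore judged against
    the union of planted features rather than per module.
    """
    planted = {f for f, m in truth.module_membership.items() if m != "background"}
    tp = len(set(nodes) & planted)
    if tp == 0 or not nodes:
        return 0.0
    precision = tp / len(set(nodes))
    recall = tp / len(planted)
    return 2 * precision * recall / (precision + recall)


def compare_regimes(
    config: PipelineConfig, regimes: tuple[str, ...] = ("none", "partial", "full")
) -> pd.DataFrame:
    """Run the pipeline under each adjustment regime and tabulate quality.

    Reports module counts, miRNA:mRNA ratios, and database/published rates
    at edge thresholds {selected, 0.001, 0.05} per regime.
    """
    rows = []
    for regime in regimes:
        cfg = dataclasses.replace(
            config, regime=regime, out_dir=f"{config.out_dir}/{regime}"
        )
        bundle = run_pipeline(cfg, write=False)
        published = sorted({m for m, _, _ in bundle.truth.planted_pairs})
        for tau_label in ("none", "0.001", "0.05"):
            if tau_label == "none":
                sub = bundle.networks
            else:
                sub = [_retrim(nw, float(tau_label)) for nw in bundle.networks]
                sub = [nw for nw in sub if nw is not None]
            _, _, pred = pair_validation_rate(
                sub, bundle.expression, bundle.target_db, "predicted"
            )
            _, _, val = pair_validation_rate(
                sub, bundle.expression, bundle.target_db, "validated"
            )
            _, _, pub = published_mirna_rate(sub, published, arm_expansion=False)
            n_mi = sum(nw.n_mirna for nw in sub)
            n_mr = sum(nw.n_mrna for nw in sub)
            rows.append(
                {
                    "regime": regime,
                    "edge_threshold": tau_label,
                    "n_modules": len(sub),
                    "n_mirna": n_mi,
                    "n_mrna": n_mr,
                    "mirna_mrna_ratio": n_mi / n_mr if n_mr else np.nan,
                    "predicted_pair_rate_pct": pred,
                    "validated_pair_rate_pct": val,
                    "published_mirna_rate_pct": pub,
                }
            )
    return pd.DataFrame(rows)


def _retrim(net, tau: float):
    """Re-apply a fixed edge threshold to an already pruned network."""
    from .prune import PrunedNetwork

    kept = net.edges[net.edges["weight"] >= tau - 1e-12]
    nodes = sorted(set(kept["source"]) | set(kept["target"]))
    if not nodes:
        return None
    return PrunedNetwork(
        net.module_id, tau, nodes, net.kinds.loc[nodes],
        kept.reset_index(drop=True), np.nan, np.nan, net.curve,
    )
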