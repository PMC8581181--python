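"""Seeded synthetic cohorts with planted miRNA-mRNA-phenotype modules.

The generator emulates the statistical structure of a blood multi-omics
cohort: negative-binomial sequencing counts with library-size variation,
clinical covariate effects (age, sex, race, smoking, white-blood-cell
percentages, batch, scanner), a few hemolysis-like outlier miRNAs with
extreme counts, and latent module factors that load on disjoint subsets of
mRNAs and miRNAs and drive a continuous phenotype.  It also fabricates the
offline fixtures the evaluation stage needs: a miRNA->target table with
predicted/validated evidence labels, and a rooted term DAG obeying the
true-path rule for enrichment tests.

All randomness flows from a single integer seed through one
``numpy.random.Generator``; no global state is touched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_target_db",
    "generate_go_fixture",
    "write_cohort",
]

BACKGROUND = "background"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-module cohort generator.

    ``loading_scale`` is the magnitude of a latent factor's effect on the
    log-mean count of its member features; ``phenotype_effects`` are the
    per-module regression coefficients of the phenotype on the latent
    factors; ``nb_dispersion`` is the negative-binomial dispersion alpha in
    the Var = mu + alpha*mu^2 parameterization.
    """

    n_subjects: int = 300
    n_mrna: int = 300
    n_mirna: int = 60
    n_modules: int = 2
    # (mRNA count, miRNA count) per module
    module_sizes: tuple[tuple[int, int], ...] = ((25, 10), (25, 10))
    loading_scale: float = 1.0
    phenotype_effects: tuple[float, ...] = (1.0, 0.8)
    phenotype_noise_sd: float = 1.0
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.1, "sex": 0.1, "smoking": 0.15}
    )
    nb_dispersion: float = 0.5
    lib_size_log_sd: float = 0.3
    n_batches: int = 3
    batch_effect_sd: float = 0.3
    n_outlier_mirna: int = 2
    outlier_total: int = 6_000_000
    seed: int = 1

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be nonnegative")
        if self.n_subjects <= 0 and self.n_modules > 0 and self.n_subjects != 0:
            raise ValueError("invalid config: no subjects but modules requested")
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if len(self.phenotype_effects) != self.n_modules:
            raise ValueError("phenotype_effects length must equal n_modules")
        if sum(m for m, _ in self.module_sizes) > self.n_mrna:
            raise ValueError("module mRNA sizes exceed n_mrna")
        if sum(m for _, m in self.module_sizes) > self.n_mirna:
            raise ValueError("module miRNA sizes exceed n_mirna")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.outlier_total <= 5_000_000:
            raise ValueError("outlier_total must exceed 5,000,000")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort.

    ``module_membership`` maps every feature ID to a module index or
    ``"background"``; ``latent_factors`` is the subject x module matrix of
    factor scores; ``planted_pairs`` is the set of (miRNA, mRNA, sign)
    regulatory pairs implied by the planted loadings.
    """

    module_membership: dict[str, object]
    latent_factors: pd.DataFrame
    planted_pairs: set[tuple[str, str, int]]

    def module_features(self, k: int) -> list[str]:
        return [f for f, m in self.module_membership.items() if m == k]

    @property
    def mirna_ids(self) -> list[str]:
        return [f for f in self.module_membership if f.startswith("mir")]

    @property
    def mrna_ids(self) -> list[str]:
        return [f for f in self.module_membership if f.startswith("gene")]


def _covariates(rng: np.random.Generator, n: int, n_batches: int) -> pd.DataFrame:
    """Clinical covariates with magnitudes typical of an older smoking cohort."""
    wbc = rng.dirichlet([6.0, 3.0, 0.5], size=n) * 100.0
    return pd.DataFrame(
        {
            "age": rng.normal(65.0, 8.0, n),
            "sex": rng.binomial(1, 0.45, n),
            "race": rng.binomial(1, 0.25, n),
            "smoking": rng.binomial(1, 0.38, n),
            "wbc_neutrophil": wbc[:, 0],
            "wbc_lymphocyte": wbc[:, 1],
            "wbc_eosinophil": wbc[:, 2],
            "batch": [f"batch{b}" for b in rng.integers(0, n_batches, n)],
            "scanner": [f"scanner{s}" for s in rng.integers(0, 2, n)],
        },
        index=[f"S{i:04d}" for i in range(n)],
    )


def _nb_counts(
    rng: np.random.Generator, log_mu: np.ndarray, alpha: float
) -> np.ndarray:
    """NB draw via gamma-Poisson mixture: Var = mu + alpha*mu^2."""
    mu = np.exp(np.clip(log_mu, None, 25.0))
    lam = mu * rng.gamma(shape=1.0 / alpha, scale=alpha, size=mu.shape)
    return rng.poisson(lam)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate one seeded cohort.

    Returns ``(mrna_counts, mirna_counts, covariates, phenotype, truth)``
    with count matrices as feature x sample integer DataFrames.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    gene_ids = [f"gene{i:04d}" for i in range(config.n_mrna)]
    mirna_ids = [f"mir{i:03d}" for i in range(config.n_mirna)]

    if n == 0:
        empty_m = pd.DataFrame(
            np.zeros((config.n_mrna, 0), dtype=np.int64), index=gene_ids
        )
        empty_mi = pd.DataFrame(
            np.zeros((config.n_mirna, 0), dtype=np.int64), index=mirna_ids
        )
        membership = {f: BACKGROUND for f in gene_ids + mirna_ids}
        truth = SyntheticTruth(membership, pd.DataFrame(), set())
        return (
            empty_m,
            empty_mi,
            pd.DataFrame(),
            pd.Series(dtype=float, name="synthetic"),
            truth,
        )

    cov = _covariates(rng, n, config.n_batches)
    lib = rng.normal(0.0, config.lib_size_log_sd, n)
    z = rng.normal(0.0, 1.0, (n, config.n_modules))

    # disjoint planted feature sets, taken from the front of each block
    membership: dict[str, object] = {f: BACKGROUND for f in gene_ids + mirna_ids}
    loadings: dict[str, float] = {}
    g_next, mi_next = 0, 0
    for k, (gk, mik) in enumerate(config.module_sizes):
        for f in gene_ids[g_next : g_next + gk]:
            membership[f] = k
            loadings[f] = config.loading_scale * rng.uniform(0.7, 1.3)
        g_next += gk
        # miRNA loadings negated so targets anti-correlate with their genes
        for f in mirna_ids[mi_next : mi_next + mik]:
            membership[f] = k
            loadings[f] = -config.loading_scale * rng.uniform(0.7, 1.3)
        mi_next += mik

    # standardized covariate effects on the log-mean
    cov_eff = np.zeros(n)
    for name, beta in config.covariate_effects.items():
        x = cov[name].to_numpy(dtype=float)
        sd = x.std()
        cov_eff = cov_eff + beta * (x - x.mean()) / (sd if sd > 0 else 1.0)

    batch_codes = cov["batch"].astype("category").cat.codes.to_numpy()

    def _block(ids: list[str], base_log_mean: float, base_sd: float) -> pd.DataFrame:
        p = len(ids)
        base = rng.normal(base_log_mean, base_sd, p)
        batch_fx = rng.normal(0.0, config.batch_effect_sd, (p, config.n_batches))
        log_mu = base[:, None] + cov_eff[None, :] + lib[None, :]
        log_mu = log_mu + batch_fx[:, batch_codes]
        for i, f in enumerate(ids):
            m = membership[f]
            if m != BACKGROUND:
                log_mu[i] += loadings[f] * z[:, m]
        counts = _nb_counts(rng, log_mu, config.nb_dispersion)
        return pd.DataFrame(counts, index=ids, columns=cov.index)

    mrna = _block(gene_ids, base_log_mean=np.log(60.0), base_sd=0.8)
    mirna = _block(mirna_ids, base_log_mean=np.log(80.0), base_sd=0.8)

    # hemolysis-like outlier miRNAs: extreme single-sample reads in
    # otherwise background features
    bg_mirna = [f for f in mirna_ids if membership[f] == BACKGROUND]
    outliers = bg_mirna[-config.n_outlier_mirna :] if config.n_outlier_mirna else []
    for f in outliers:
        j = rng.integers(0, n)
        mirna.loc[f, mirna.columns[j]] = config.outlier_total + int(
            rng.integers(0, 1_000_000)
        )

    gamma = {"age": 0.2, "smoking": 0.3}
    pheno = np.zeros(n)
    for k, beta in enumerate(config.phenotype_effects):
        pheno = pheno + beta * z[:, k]
    for name, g in gamma.items():
        x = cov[name].to_numpy(dtype=float)
        sd = x.std()
        pheno = pheno + g * (x - x.mean()) / (sd if sd > 0 else 1.0)
    pheno = pheno + rng.normal(0.0, config.phenotype_noise_sd, n)
    phenotype = pd.Series(pheno, index=cov.index, name="synthetic")

    pairs = {
        (mi, g, -1)
        for k in range(config.n_modules)
        for mi in mirna_ids
        if membership[mi] == k
        for g in gene_ids
        if membership[g] == k
    }
    latent = pd.DataFrame(
        z, index=cov.index, columns=[f"z{k}" for k in range(config.n_modules)]
    )
    truth = SyntheticTruth(membership, latent, pairs)
    return mrna, mirna, cov, phenotype, truth


def generate_target_db(
    truth: SyntheticTruth,
    extra_random_pairs: int = 0,
    frac_validated: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Offline miRNA->target table: every planted negative pair plus decoys.

    Decoys are drawn without replacement from the non-planted miRNA x mRNA
    combinations.  Each row carries an evidence label (``predicted`` or
    ``validated``) and a source tag, mirroring an offline snapshot of a
    target-prediction aggregate.
    """
    if not 0.0 <= frac_validated <= 1.0:
        raise ValueError("frac_validated must be in [0, 1]")
    rng = np.random.default_rng(seed)
    planted = sorted((mi, g) for mi, g, s in truth.planted_pairs if s < 0)
    all_pairs = [(mi, g) for mi in truth.mirna_ids for g in truth.mrna_ids]
    pool = sorted(set(all_pairs) - set(planted))
    if extra_random_pairs > len(pool):
        raise ValueError(
            f"requested {extra_random_pairs} decoys but only {len(pool)} "
            "non-planted combinations exist"
        )
    decoy_idx = rng.choice(len(pool), size=extra_random_pairs, replace=False)
    rows = planted + [pool[i] for i in sorted(decoy_idx)]
    evidence = np.where(
        rng.random(len(rows)) < frac_validated, "validated", "predicted"
    )
    return pd.DataFrame(
        {
            "mirna": [r[0] for r in rows],
            "gene": [r[1] for r in rows],
            "evidence": evidence,
            "source": "synthetic-targetdb",
        }
    )


def generate_go_fixture(
    genes: list[str], n_terms: int, depth: int, seed: int = 0
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Rooted term DAG with gene annotations obeying the true-path rule.

    Returns ``(terms, parents)``: term -> gene set and term -> parent-term
    set.  The root is annotated to all genes; each child's gene set is a
    random subset of one parent's, so child genes are a subset of parent
    genes on every edge by construction.
    """
    if not genes:
        raise ValueError("gene list must be nonempty")
    if n_terms < 1 or depth < 1:
        raise ValueError("n_terms and depth must be >= 1")
    rng = np.random.default_rng(seed)
    terms: dict[str, set[str]] = {"T0000": set(genes)}
    parents: dict[str, set[str]] = {"T0000": set()}
    levels: list[list[str]] = [["T0000"]]
    tid = 1
    while tid < n_terms:
        level = []
        for _ in range(min(n_terms - tid, max(1, len(levels[-1]) * 2))):
            parent = levels[-1][rng.integers(0, len(levels[-1]))]
            pg = sorted(terms[parent])
            size = max(1, int(np.ceil(len(pg) * rng.uniform(0.3, 0.7))))
            sub = set(rng.choice(pg, size=size, replace=False))
            name = f"T{tid:04d}"
            terms[name] = sub
            parents[name] = {parent}
            level.append(name)
            tid += 1
            if tid >= n_terms:
                break
        levels.append(level)
        if len(levels) > depth and tid < n_terms:
            # keep attaching to the deepest level once target depth reached
            levels[-1] = levels[-1] or levels[-2]
    return terms, parents


def write_cohort(
    out_dir: str | Path,
    mrna: pd.DataFrame,
    mirna: pd.DataFrame,
    covariates: pd.DataFrame,
    phenotype: pd.Series,
    truth: SyntheticTruth,
) -> None:
    """Write a cohort as TSV/JSON files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mrna.to_csv(out / "mrna_counts.tsv", sep="\t")
    mirna.to_csv(out / "mirna_counts.tsv", sep="\t")
    covariates.to_csv(out / "covariates.tsv", sep="\t")
    phenotype.rename("phenotype").to_csv(out / "phenotype.tsv", sep="\t")
    payload = {
        "module_membership": {k: v for k, v in truth.module_membership.items()},
        "planted_pairs": sorted(list(p) for p in truth.planted_pairs),
        "latent_factors": truth.latent_factors.round(6).to_dict(orient="index"),
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))
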