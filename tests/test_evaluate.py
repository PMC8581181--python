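"""Quality metrics, single-omics tests, cohort summaries, spirometry."""

import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from phenonet.evaluate import (
    classify_spirometry,
    cohort_summary,
    correlation_range_summary,
    expand_arms,
    load_target_db,
    network_vs_single_overlap,
    pair_validation_rate,
    published_mirna_rate,
    rate_percent,
    single_omics_correlations,
)
from phenonet.prune import PrunedNetwork


def _network(edges, kinds):
    """Minimal pruned-network stub from an edge list and kind map."""
    nodes = sorted(kinds)
    df = pd.DataFrame(edges, columns=["source", "target", "weight"])
    df["source_kind"] = df["source"].map(kinds)
    df["target_kind"] = df["target"].map(kinds)
    return PrunedNetwork(
        1, 0.001, nodes, pd.Series(kinds), df, 0.5, 0.01, pd.DataFrame()
    )


def _anti_expr(pairs, n=12, seed=0):
    """Expression where each (miRNA, gene) pair is exactly anti-correlated."""
    rng = np.random.default_rng(seed)
    rows, idx = [], []
    base = {}
    for mi, g in pairs:
        if g not in base:
            base[g] = rng.normal(size=n)
            rows.append(base[g]); idx.append(g)
        if mi not in base:
            base[mi] = -base[g]
            rows.append(base[mi]); idx.append(mi)
    return pd.DataFrame(rows, index=idx, columns=[f"s{j}" for j in range(n)])


class TestPairValidation:
    def test_toy_three_of_ten_found(self):
        pairs = [(f"mir{i}", f"gene{i}") for i in range(10)]
        kinds = {}
        edges = []
        for mi, g in pairs:
            kinds[mi] = "miRNA"
            kinds[g] = "mRNA"
            edges.append((mi, g, 0.01))
        net = _network(edges, kinds)
        expr = _anti_expr(pairs)
        db = load_target_db(pd.DataFrame(
            {"mirna": ["mir0", "mir1", "mir2"],
             "gene": ["gene0", "gene1", "gene2"],
             "evidence": "validated", "source": "t"}
        ))
        n, found, rate = pair_validation_rate([net], expr, db, "validated")
        assert (n, found, rate) == (10, 3, 30.0)

    def test_empty_networks_undefined_rate(self):
        db = load_target_db(pd.DataFrame(
            {"mirna": ["m"], "gene": ["g"], "evidence": ["predicted"]}
        ))
        assert pair_validation_rate([], pd.DataFrame(), db) == (0, 0, None)

    def test_invariant_to_db_row_order_and_duplicates(self):
        pairs = [("mirA", "geneA"), ("mirB", "geneB")]
        kinds = {"mirA": "miRNA", "geneA": "mRNA", "mirB": "miRNA", "geneB": "mRNA"}
        edges = [(m, g, 0.02) for m, g in pairs]
        net = _network(edges, kinds)
        expr = _anti_expr(pairs)
        rows = pd.DataFrame(
            {"mirna": ["mirA", "mirB"], "gene": ["geneA", "geneB"],
             "evidence": "predicted", "source": "t"}
        )
        shuffled = pd.concat([rows.iloc[::-1], rows]).reset_index(drop=True)
        r1 = pair_validation_rate([net], expr, load_target_db(rows))
        r2 = pair_validation_rate([net], expr, load_target_db(shuffled))
        assert r1 == r2

    def test_printed_operand_baseline_rounds_to_point_one(self):
        # database-wide union of predicted+validated pairs over all
        # testable combinations in a filtered cohort
        assert round(rate_percent(6456, 6_412_400), 1) == 0.1


class TestPublishedMirnas:
    def _net(self):
        kinds = {"miR-1-5p": "miRNA", "miR-2-3p": "miRNA", "geneX": "mRNA"}
        edges = [("miR-1-5p", "geneX", 0.01), ("miR-2-3p", "geneX", 0.01)]
        return _network(edges, kinds)

    def test_armless_entry_matches_both_arms(self):
        n, matched, rate = published_mirna_rate([self._net()], ["miR-1"])
        assert (n, matched, rate) == (2, 1, 50.0)

    def test_empty_list_matches_nothing(self):
        assert published_mirna_rate([self._net()], [])[1] == 0

    def test_explicit_arm_matches_only_that_arm(self):
        n, matched, _ = published_mirna_rate([self._net()], ["miR-2-5p"])
        assert matched == 0
        n, matched, _ = published_mirna_rate([self._net()], ["miR-2-3p"])
        assert matched == 1

    def test_expansion_never_decreases_matches(self):
        names = ["miR-1", "miR-2-3p", "miR-9"]
        net = self._net()
        m_with = published_mirna_rate([net], names, arm_expansion=True)[1]
        m_without = published_mirna_rate([net], names, arm_expansion=False)[1]
        assert m_with >= m_without
        assert expand_arms(["miR-5"]) == {"miR-5-3p", "miR-5-5p"}


class TestSingleOmics:
    def test_feature_identical_to_phenotype_significant(self, rng):
        y = pd.Series(rng.normal(size=30), index=[f"s{j}" for j in range(30)])
        expr = pd.DataFrame([y.to_numpy(), rng.normal(size=30)],
                            index=["same", "noise"], columns=y.index)
        out = single_omics_correlations(expr, y).set_index("feature")
        assert out.loc["same", "r"] == pytest.approx(1.0)
        assert bool(out.loc["same", "significant"])

    def test_bh_step_up_hand_case(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_brute_force_step_up(self, rng):
        def brute_force_bh(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        for size in range(1, 11):
            p = rng.uniform(size=size)
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], brute_force_bh(p),
                rtol=1e-12,
            )

    def test_null_features_rarely_called(self):
        rng = np.random.default_rng(7)
        y = pd.Series(rng.normal(size=50), index=[f"s{j}" for j in range(50)])
        expr = pd.DataFrame(
            rng.normal(size=(200, 50)),
            index=[f"f{i}" for i in range(200)], columns=y.index,
        )
        out = single_omics_correlations(expr, y)
        assert out["significant"].sum() <= 2

    def test_constant_feature_excluded(self, rng):
        y = pd.Series(rng.normal(size=20), index=[f"s{j}" for j in range(20)])
        expr = pd.DataFrame(
            [np.ones(20), rng.normal(size=20)],
            index=["const", "ok"], columns=y.index,
        )
        out = single_omics_correlations(expr, y).set_index("feature")
        assert np.isnan(out.loc["const", "r"])
        assert not np.isnan(out.loc["ok", "p_adj"])


class TestOverlapAndRanges:
    def test_overlap_counts_match_set_oracle(self, rng):
        kinds = {"mirA": "miRNA", "geneA": "mRNA", "geneB": "mRNA"}
        net = _network(
            [("mirA", "geneA", 0.01), ("mirA", "geneB", 0.01)], kinds
        )
        single = pd.DataFrame(
            {"feature": ["geneA", "geneB", "mirA", "geneC"],
             "significant": [True, False, False, True]}
        )
        out = network_vs_single_overlap([net], single).set_index("kind")
        assert out.loc["mRNA", "n_single_significant"] == 1
        assert out.loc["mRNA", "n_network_only"] == 1
        assert out.loc["miRNA", "n_single_significant"] == 0

    def test_column_equal_to_phenotype_gives_max_one(self, rng):
        y = pd.Series(rng.normal(size=15), index=[f"s{j}" for j in range(15)])
        X1 = pd.DataFrame(
            [y.to_numpy(), rng.normal(size=15)], index=["a", "b"], columns=y.index
        )
        X2 = pd.DataFrame(
            rng.normal(size=(2, 15)), index=["m1", "m2"], columns=y.index
        )
        out = correlation_range_summary(X1, X2, y).set_index("pair_type")
        assert out.loc["mRNA-phenotype", "max"] == pytest.approx(1.0)

    def test_summaries_match_brute_force_all_pairs(self, rng):
        X1 = pd.DataFrame(rng.normal(size=(3, 20)),
                          index=list("abc"), columns=[f"s{j}" for j in range(20)])
        X2 = pd.DataFrame(rng.normal(size=(3, 20)),
                          index=list("xyz"), columns=X1.columns)
        y = pd.Series(rng.normal(size=20), index=X1.columns)
        out = correlation_range_summary(X1, X2, y).set_index("pair_type")
        vals = [
            np.corrcoef(X1.loc[i], X2.loc[j])[0, 1]
            for i in X1.index for j in X2.index
        ]
        np.testing.assert_allclose(
            out.loc["mRNA-miRNA", ["min", "q1", "median", "q3", "max"]].astype(float),
            np.percentile(vals, [0, 25, 50, 75, 100]),
        )

    def test_empty_mirna_block_reported_missing(self, rng):
        X1 = pd.DataFrame(rng.normal(size=(2, 10)),
                          index=["a", "b"], columns=[f"s{j}" for j in range(10)])
        X2 = pd.DataFrame(np.empty((0, 10)), columns=X1.columns)
        y = pd.Series(rng.normal(size=10), index=X1.columns)
        out = correlation_range_summary(X1, X2, y).set_index("pair_type")
        assert out.loc["miRNA-phenotype", "n_pairs"] == 0
        assert np.isnan(out.loc["miRNA-phenotype", "median"])


class TestSpirometry:
    @pytest.mark.parametrize(
        "fev1pp,ratio,expected",
        [
            (85, 0.65, "GOLD1"),
            (45, 0.60, "GOLD3"),
            (70, 0.80, "PRISm"),
            (90, 0.75, "normal"),
            (60, 0.55, "GOLD2"),
            (20, 0.40, "GOLD4"),
        ],
    )
    def test_printed_cutpoints(self, fev1pp, ratio, expected):
        assert classify_spirometry(fev1pp, ratio) == expected

    def test_partitions_the_plane(self):
        labels = {"normal", "PRISm", "GOLD1", "GOLD2", "GOLD3", "GOLD4"}
        for fev1pp, ratio in itertools.product(
            np.arange(0, 131, 5), np.arange(0, 1.01, 0.05)
        ):
            assert classify_spirometry(float(fev1pp), float(ratio)) in labels


class TestCohortSummary:
    def _cohort(self):
        rng = np.random.default_rng(0)
        n = {"normal": 183, "COPD": 169, "PRISm": 52}
        rows = []
        groups = []
        males = {"normal": 79, "COPD": 84, "PRISm": 24}
        smokers = {"normal": 60, "COPD": 64, "PRISm": 27}
        for g, size in n.items():
            for i in range(size):
                rows.append(
                    {"sex": 1 if i < males[g] else 0,
                     "smoking": 1 if i < smokers[g] else 0,
                     "age": rng.normal(65, 8)}
                )
                groups.append(g)
        idx = [f"S{i}" for i in range(len(rows))]
        cov = pd.DataFrame(rows, index=idx)
        groups = pd.Series(groups, index=idx)
        return cov, groups

    def test_percentages_match_printed_table(self):
        cov, groups = self._cohort()
        out = cohort_summary(
            cov[["sex", "smoking"]], pd.DataFrame(index=cov.index), groups,
            categorical=["sex", "smoking"],
        ).set_index("variable")
        assert out.loc["sex", "normal"] == "79 (43.2)"
        assert out.loc["smoking", "PRISm"] == "27 (51.9)"

    def test_group_sizes_sum_to_cohort(self):
        cov, groups = self._cohort()
        assert (groups == "COPD").sum() == 169
        assert len(groups) == 404

    def test_single_group_comparison_missing(self):
        cov, groups = self._cohort()
        one = groups[groups == "PRISm"]
        out = cohort_summary(
            cov.loc[one.index, ["age"]], pd.DataFrame(index=one.index), one
        )
        assert np.isnan(out.set_index("variable").loc["age", "p_value"])
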