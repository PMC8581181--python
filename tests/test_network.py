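"""Robust adjacency construction, module detection, edge signs."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from phenonet.network import (
    NetworkModule,
    SimilarityMatrix,
    assign_edge_signs,
    detect_modules,
    robust_adjacency,
)
from phenonet.smcca import SmccaParams, smcca_weights, standardize_columns


def _problem(rng, n=40, p1=6, p2=4):
    X1 = rng.normal(size=(n, p1))
    X2 = rng.normal(size=(n, p2))
    Y = rng.normal(size=n)
    return X1, X2, Y


def _ids(p1, p2):
    return [f"gene{i}" for i in range(p1)], [f"mir{i}" for i in range(p2)]


class TestRobustAdjacency:
    def test_no_subsampling_equals_outer_product(self, rng):
        X1, X2, Y = _problem(rng)
        params = SmccaParams(l1=0.8, l2=0.8)
        g, m = _ids(6, 4)
        sim = robust_adjacency(
            X1, X2, Y, params, g, m, prop1=1.0, prop2=1.0, reps=1, seed=0
        )
        fit = smcca_weights(
            standardize_columns(X1), standardize_columns(X2), Y, params
        )
        w = np.concatenate([fit.w1, fit.w2])
        expected = np.abs(np.outer(w, w))
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(sim.values.to_numpy(), expected, atol=1e-12)

    def test_symmetric_unit_range_and_reproducible(self, rng):
        X1, X2, Y = _problem(rng)
        g, m = _ids(6, 4)
        params = SmccaParams(l1=0.8, l2=0.8)
        sim1 = robust_adjacency(X1, X2, Y, params, g, m, reps=25, seed=7)
        sim2 = robust_adjacency(X1, X2, Y, params, g, m, reps=25, seed=7)
        A = sim1.values.to_numpy()
        assert np.abs(A - A.T).max() < 1e-12
        assert A.min() >= 0.0 and A.max() <= 1.0
        assert np.diagonal(A).max() == 0.0
        pd.testing.assert_frame_equal(sim1.values, sim2.values)

    def test_within_module_exceeds_between(self):
        from phenonet.synthetic import SimulationConfig, generate_cohort

        cfg = SimulationConfig(
            n_subjects=150, n_mrna=60, n_mirna=15, n_modules=1,
            module_sizes=((12, 5),), phenotype_effects=(1.0,), seed=1,
        )
        mrna, mirna, cov, y, truth = generate_cohort(cfg)
        X1 = np.log1p(mrna).T.to_numpy()
        X2 = np.log1p(mirna).T.to_numpy()
        sim = robust_adjacency(
            X1, X2, y.to_numpy(), SmccaParams(), list(mrna.index),
            list(mirna.index), reps=50, seed=1,
        )
        planted = set(truth.module_features(0))
        ids = sim.values.index
        mask = np.array([f in planted for f in ids])
        A = sim.values.to_numpy()
        iu = np.triu_indices(len(ids), 1)
        within = A[iu][mask[iu[0]] & mask[iu[1]]]
        between = A[iu][mask[iu[0]] ^ mask[iu[1]]]
        assert within.mean() > between.mean()


class TestDetectModules:
    @staticmethod
    def _block_sim(sizes, rng=None, noise=0.0):
        p = sum(sizes)
        A = np.zeros((p, p))
        start = 0
        labels = np.empty(p, dtype=int)
        for k, s in enumerate(sizes):
            A[start : start + s, start : start + s] = 1.0
            labels[start : start + s] = k
            start += s
        if rng is not None:
            noise_m = rng.uniform(0, noise, size=(p, p))
            A = np.clip(A + (noise_m + noise_m.T) / 2, 0, 1)
        np.fill_diagonal(A, 0.0)
        ids = [f"f{i:03d}" for i in range(p)]
        kinds = pd.Series(["mRNA"] * p, index=ids)
        df = pd.DataFrame(A, index=ids, columns=ids)
        return SimilarityMatrix(df, kinds, (df * 0 + 1).astype(int)), labels

    def test_two_perfect_blocks_recovered_exactly(self):
        sim, labels = self._block_sim([6, 8])
        mods = detect_modules(sim, n_modules=2, min_size=2)
        got = [set(m.nodes) for m in mods]
        ids = np.asarray(sim.values.index)
        expected = [set(ids[labels == k]) for k in (0, 1)]
        assert sorted(got, key=len) == sorted(expected, key=len)

    def test_modules_disjoint_subsets(self, rng):
        p = 30
        M = rng.uniform(0, 1, size=(p, p))
        A = np.clip((M + M.T) / 2, 0, 1)
        np.fill_diagonal(A, 0)
        ids = [f"f{i}" for i in range(p)]
        df = pd.DataFrame(A, index=ids, columns=ids)
        sim = SimilarityMatrix(df, pd.Series(["mRNA"] * p, index=ids), df * 0 + 1)
        mods = detect_modules(sim, n_modules=4, min_size=2)
        seen = set()
        for m in mods:
            assert not (set(m.nodes) & seen)
            seen |= set(m.nodes)
        assert seen <= set(ids)

    def test_noisy_planted_blocks_high_ari(self):
        rng = np.random.default_rng(1)
        # two dense planted blocks over a weak background, as the subsampled
        # canonical weights produce for phenotype-linked modules
        p = 40
        A = rng.uniform(0, 0.002, size=(p, p))
        A = (A + A.T) / 2
        labels = np.zeros(p, dtype=int)
        A[:12, :12] = rng.uniform(0.01, 0.03, size=(12, 12))
        A[12:22, 12:22] = rng.uniform(0.01, 0.03, size=(10, 10))
        A = np.triu(A, 1)
        A = A + A.T
        labels[:12] = 1
        labels[12:22] = 2
        ids = [f"f{i:02d}" for i in range(p)]
        df = pd.DataFrame(A, index=ids, columns=ids)
        sim = SimilarityMatrix(df, pd.Series(["mRNA"] * p, index=ids), df * 0 + 1)
        mods = detect_modules(sim, cut_height=0.99, min_size=3)
        pred = np.zeros(p, dtype=int)
        for m in mods:
            for n in m.nodes:
                pred[ids.index(n)] = m.module_id
        assert adjusted_rand_score(labels, pred) >= 0.9

    def test_invariant_to_feature_ordering(self, rng):
        sim, _ = self._block_sim([5, 7], rng=rng, noise=0.05)
        perm = rng.permutation(len(sim.values))
        ids = np.asarray(sim.values.index)[perm]
        df = sim.values.iloc[perm, perm]
        sim_p = SimilarityMatrix(df, sim.kinds.iloc[perm], df * 0 + 1)
        a = [sorted(m.nodes) for m in detect_modules(sim, n_modules=2, min_size=2)]
        b = [sorted(m.nodes) for m in detect_modules(sim_p, n_modules=2, min_size=2)]
        assert sorted(map(tuple, a)) == sorted(map(tuple, b))


class TestEdgeSigns:
    def _module(self, adjacency, ids, kinds=None):
        kinds = kinds or ["mRNA"] * len(ids)
        df = pd.DataFrame(adjacency, index=ids, columns=ids)
        return NetworkModule(1, list(ids), pd.Series(kinds, index=ids), df)

    def test_identical_rows_positive(self):
        ids = ["a", "b"]
        mod = self._module([[0, 0.5], [0.5, 0]], ids)
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [1.0, 2, 3, 4]], index=ids,
            columns=list("wxyz"),
        )
        out = assign_edge_signs(mod, expr)
        assert list(out.edges["sign"]) == ["+"]

    def test_negated_row_negative(self):
        ids = ["a", "b"]
        mod = self._module([[0, 0.5], [0.5, 0]], ids)
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [-1.0, -2, -3, -4]], index=ids,
            columns=list("wxyz"),
        )
        out = assign_edge_signs(mod, expr)
        assert list(out.edges["sign"]) == ["-"]

    def test_signs_match_correlation_matrix(self, rng):
        ids = [f"f{i}" for i in range(4)]
        A = np.full((4, 4), 0.2)
        np.fill_diagonal(A, 0)
        mod = self._module(A, ids)
        expr = pd.DataFrame(
            rng.normal(size=(4, 12)), index=ids,
            columns=[f"s{j}" for j in range(12)],
        )
        out = assign_edge_signs(mod, expr)
        corr = np.corrcoef(expr.to_numpy())
        for _, row in out.edges.iterrows():
            i, j = ids.index(row["source"]), ids.index(row["target"])
            assert row["sign"] == ("-" if corr[i, j] < 0 else "+")

    def test_constant_feature_rejected(self):
        ids = ["a", "b"]
        mod = self._module([[0, 0.5], [0.5, 0]], ids)
        expr = pd.DataFrame(
            [[1.0, 1, 1, 1], [1.0, 2, 3, 4]], index=ids, columns=list("wxyz")
        )
        with pytest.raises(ValueError, match="a"):
            assign_edge_signs(mod, expr)
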