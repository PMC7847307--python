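"""Single-cell embedding, modules, deviation scores and cell calls."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

import gsckit as g


class TestTfidfLsi:
    def test_duplicate_cells_identical_rows(self, rng):
        X = rng.poisson(1.0, size=(30, 80))
        X[5] = X[2]
        emb = g.tfidf_lsi(sp.csr_matrix(X), n_dims=5)
        np.testing.assert_allclose(emb[5], emb[2], atol=1e-8)

    def test_seeded_determinism(self, rng):
        X = sp.csr_matrix(rng.poisson(1.0, size=(40, 60)))
        e1 = g.tfidf_lsi(X, n_dims=8, seed=3)
        e2 = g.tfidf_lsi(X, n_dims=8, seed=3)
        np.testing.assert_array_equal(e1, e2)

    def test_svd_captures_leading_variance(self, rng):
        # the retained components carry at least as much energy as the same
        # count of trailing dense-SVD components (Eckart-Young)
        X = rng.poisson(2.0, size=(25, 40)).astype(float)
        n_dims = 5
        emb = g.tfidf_lsi(sp.csr_matrix(X), n_dims=n_dims, seed=0)
        # reconstruct the transformed matrix used internally
        depth = X.sum(axis=1, keepdims=True)
        tf = X / depth
        idf = X.shape[0] / (1.0 + (X > 0).sum(axis=0))
        mat = np.log1p(tf * idf * 1e4)
        sv_dense = np.linalg.svd(mat, compute_uv=False)
        energy = (emb**2).sum()
        optimum = (sv_dense[1 : n_dims + 1] ** 2).sum()  # components 2..n_dims+1
        assert energy <= optimum + 1e-6
        assert energy >= 0.99 * optimum

    def test_dim_bounds(self, rng):
        X = sp.csr_matrix(rng.poisson(1.0, size=(10, 12)))
        with pytest.raises(ValueError):
            g.tfidf_lsi(X, n_dims=10)


class TestClusterCells:
    def test_elbow_on_hand_sequence(self):
        wss = {1: 100.0, 2: 40.0, 3: 20.0, 4: 18.0, 5: 17.0}
        assert g.elbow_k(wss) == 3

    def test_three_blobs_recovered(self, rng):
        X = np.vstack(
            [rng.normal(c, 0.1, size=(40, 3)) for c in ((0, 0, 0), (5, 0, 0), (0, 5, 0))]
        )
        cl = g.cluster_cells(X, kmin=2, kmax=8)
        assert cl.n_modules == 3
        truth = [0] * 40 + [1] * 40 + [2] * 40
        assert g.cluster_agreement(cl.module, truth) == 1.0

    def test_permutation_invariance(self, rng):
        X = np.vstack([rng.normal(c, 0.2, size=(30, 4)) for c in (0, 6)])
        perm = rng.permutation(len(X))
        c1 = g.cluster_cells(X, kmin=2, kmax=6)
        c2 = g.cluster_cells(X[perm], kmin=2, kmax=6)
        assert g.cluster_agreement(c1.module[perm], c2.module) == 1.0


class TestDeviationScores:
    def test_full_catalog_signature_zero_raw(self, cell_data):
        cells, _ = cell_data
        sig = g.Signature("all", frozenset(range(cells.n_regions)))
        dev = g.deviation_scores(cells, sig, n_background=5, seed=1)
        np.testing.assert_allclose(dev.raw[dev.valid], 0.0, atol=1e-12)

    def test_deviation_conservation(self, cell_devs, cell_data):
        cells, _ = cell_data
        depth = cells.cell_depth
        total = depth.sum()
        for dev in cell_devs.values():
            # sum over cells of (obs - exp) = sum raw * exp = 0 exactly
            frac_weighted = np.nansum(dev.raw * depth)
            assert abs(frac_weighted) / total < 1e-9

    def test_planted_cells_score_higher(self, cell_devs, cell_data):
        _, truth = cell_data
        for state, dev in cell_devs.items():
            auroc = roc_auc_score(truth.cell_state == state, dev.z)
            assert auroc >= 0.95

    def test_background_matching_calibrates_gc_biased_null(self, cfg):
        # with GC-accessibility coupling, a GC-extreme null signature keeps
        # |mean z| small because backgrounds are matched on GC
        cells, _ = g.simulate_cell_matrix(cfg.with_(gc_bias=1.0, effect_size=1.0), seed=31)
        top_gc = np.argsort(cells.region_gc)[-100:]
        sig = g.Signature("gc_null", frozenset(top_gc.tolist()))
        dev = g.deviation_scores(cells, sig, n_background=50, seed=5)
        assert abs(np.nanmean(dev.z)) < 0.1

    def test_signature_outside_catalog_errors(self, cell_data):
        cells, _ = cell_data
        with pytest.raises(ValueError):
            g.deviation_scores(cells, g.Signature("bad", frozenset({cells.n_regions + 5})))


class TestCellCalls:
    def test_classification_accuracy_on_planted_states(self, cell_devs, cell_data):
        _, truth = cell_data
        calls = g.classify_cells(cell_devs, alpha=0.05)
        called = [(i, cs) for i, cs in enumerate(calls) if cs]
        correct = sum(truth.cell_state[i] in cs for i, cs in called)
        assert correct / len(called) >= 0.9

    def test_alpha_zero_no_assignments(self, cell_devs):
        calls = g.classify_cells(cell_devs, alpha=0.0)
        assert all(len(cs) == 0 for cs in calls)

    def test_null_effect_gives_few_calls(self, cfg):
        cells, truth = g.simulate_cell_matrix(cfg.with_(effect_size=1.0), seed=41)
        regs = truth.state_signature_regions["NPC"]
        dev = g.deviation_scores(cells, g.Signature("NPC", frozenset(regs.tolist())), seed=2)
        pos = g.call_positive(dev, alpha=0.05)
        assert pos.mean() <= 0.05  # BH under the global null

    def test_stem_recall_and_fpr(self, cell_data):
        cells, truth = cell_data
        sig = g.Signature("stem", frozenset(truth.stem_regions.tolist()))
        dev = g.deviation_scores(cells, sig, n_background=50, seed=9)
        pos = g.call_positive(dev, alpha=0.05)
        stem = truth.stem_flags
        recall = pos[stem].mean()
        fpr = pos[~stem].mean()
        assert recall >= 0.8
        assert fpr <= 0.05 * 1.5

    def test_two_stem_signatures_correlate(self, cell_data):
        cells, truth = cell_data
        regs = truth.stem_regions
        a = g.Signature("stem19", frozenset(regs[: 2 * len(regs) // 3].tolist()))
        b = g.Signature("gsc_shared", frozenset(regs[len(regs) // 3 :].tolist()))
        za = g.deviation_scores(cells, a, seed=3).z
        zb = g.deviation_scores(cells, b, seed=4).z
        r, p = g.signature_correlation(za, zb)
        assert r > 0.5
        assert p < 1e-6


class TestModuleDominance:
    def _clusters(self, n):
        return g.CellClusters(module=np.zeros(n, dtype=int), n_modules=1)

    def _calls(self, counts):
        calls = []
        for state, c in counts.items():
            calls += [{state}] * c
        calls += [set()] * 0
        return calls

    def test_single_state_dominates(self):
        calls = self._calls({"NPC": 10, "OPC": 4, "MES": 1})
        calls += [set()]  # an unassigned cell
        res = g.module_dominance(self._clusters(len(calls)), calls)
        assert res[0] == ("single", ("NPC",))

    def test_pair_dominates(self):
        calls = self._calls({"NPC": 6, "OPC": 5, "MES": 2, "AC": 1})
        res = g.module_dominance(self._clusters(len(calls)), calls)
        assert res[0] == ("pair", ("NPC", "OPC"))

    def test_all_equal_mixed(self):
        calls = self._calls({"NPC": 3, "OPC": 3, "MES": 3, "AC": 3})
        res = g.module_dominance(self._clusters(len(calls)), calls)
        assert res[0][0] == "mixed"

    def test_empty_module_mixed(self):
        clusters = g.CellClusters(module=np.zeros(2, dtype=int), n_modules=2)
        res = g.module_dominance(clusters, [{"NPC"}, {"NPC"}])
        assert res[1][0] == "mixed"


class TestSignatureCorrelation:
    def test_perfect_and_inverse(self, rng):
        z = rng.normal(size=50)
        assert g.signature_correlation(z, z)[0] == pytest.approx(1.0)
        assert g.signature_correlation(z, -z)[0] == pytest.approx(-1.0)

    def test_hand_computation(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        r, p = g.signature_correlation(a, b)
        # textbook Pearson r and two-sided t-test with df = 3
        r_hand = np.corrcoef(a, b)[0, 1]
        from scipy import stats

        t = r_hand * np.sqrt(3 / (1 - r_hand**2))
        p_hand = 2 * stats.t.sf(abs(t), df=3)
        assert r == pytest.approx(r_hand)
        assert p == pytest.approx(p_hand)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            g.signature_correlation(np.ones(5), np.arange(5.0))


class TestOverlapTest:
    def test_closed_form_toy(self):
        # universe 10, |a|=5, |b|=4, overlap 4: p = C(5,4)*C(5,0)/C(10,4) = 5/210
        a = set(range(5))
        b = {0, 1, 2, 3}
        assert g.overlap_test(a, b, 10) == pytest.approx(5 / 210)

    def test_enumeration_oracle(self):
        from math import comb

        a = set(range(6))
        b = set(range(4, 10))
        universe = 12
        obs = len(a & b)
        p_enum = sum(
            comb(len(a), k) * comb(universe - len(a), len(b) - k) for k in range(obs, min(len(a), len(b)) + 1)
        ) / comb(universe, len(b))
        assert g.overlap_test(a, b, universe) == pytest.approx(p_enum)

    def test_forced_overlap_p_one(self):
        a = set(range(10))
        b = {3, 4}
        assert g.overlap_test(a, b, 10) == pytest.approx(1.0)
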