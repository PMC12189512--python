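"""AUCell scoring, RSS/RSSZ, CSI, module detection and importance ranking."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crossova.exceptions import ConfigurationError
from crossova.regulons import (
    aucell_score,
    compute_csi,
    compute_rss,
    csi_from_pcc,
    detect_modules,
    extract_targets,
    infer_importance,
)

from conftest import make_adata


def _expr_adata(x, gene_ids=None):
    adata = make_adata(np.zeros_like(x, dtype=int), gene_ids=gene_ids)
    adata.X = sp.csr_matrix(np.asarray(x, dtype=float))
    return adata


class TestAucell:
    def test_top_ranked_set_scores_one(self):
        # 3-gene set occupies ranks 1-3 of 10 genes; threshold ceil(0.5*10)=5
        x = np.array([[10, 9, 8, 1, 1, 1, 0, 0, 0, 0]], dtype=float)
        adata = _expr_adata(x)
        s = aucell_score(adata, {"r": ["g1", "g2", "g3"]}, top_frac=0.5)
        assert s.iloc[0, 0] == 1.0

    def test_set_below_threshold_scores_zero(self):
        x = np.array([[10, 9, 8, 7, 6, 5, 1, 2, 3]], dtype=float)
        adata = _expr_adata(x)
        s = aucell_score(adata, {"r": ["g7", "g8", "g9"]}, top_frac=1 / 3)
        assert s.iloc[0, 0] == 0.0

    def test_matches_stepwise_recovery_curve(self):
        """10-gene cell, 3-gene set, threshold 5: enumerate the curve."""
        x = np.array([[5.0, 1.0, 9.0, 2.0, 8.0, 0.5, 7.0, 0.1, 3.0, 4.0]])
        adata = _expr_adata(x)
        members = ["g1", "g3", "g8"]
        s = aucell_score(adata, {"r": members}, top_frac=0.5)
        # ranks (descending): g3=1, g5=2, g7=3, g1=4, g10=5, ...
        order = sorted(range(10), key=lambda j: -x[0, j])
        hits = [1 if f"g{j + 1}" in members else 0 for j in order[:5]]
        curve = np.cumsum(hits)
        auc = curve.sum()
        max_auc = sum(min(i, 3) for i in range(1, 6))
        assert s.iloc[0, 0] == pytest.approx(auc / max_auc, abs=1e-12)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        x = rng.random((6, 30))
        regs = {"a": [f"g{j}" for j in range(1, 8)], "b": [f"g{j}" for j in range(10, 20)]}
        s1 = aucell_score(_expr_adata(x), regs)
        s2 = aucell_score(_expr_adata(np.exp(5 * x)), regs)
        np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-12)

    def test_deterministic_tie_break_by_gene_id(self):
        x = np.ones((1, 6))
        adata = _expr_adata(x)
        s = aucell_score(adata, {"r": ["g1", "g2"]}, top_frac=0.5)
        # all tied: stable order is ascending gene id, so g1,g2 take ranks 1,2
        assert s.iloc[0, 0] == 1.0

    def test_empty_regulon_flagged(self):
        adata = _expr_adata(np.random.default_rng(1).random((3, 10)))
        with pytest.warns(UserWarning, match="absent"):
            s = aucell_score(adata, {"r": ["nope1", "nope2"]})
        assert s.attrs["undefined"] == ["r"]
        assert s.isna().all(axis=None)


class TestRSS:
    def test_perfectly_specific_regulon_scores_one(self):
        act = pd.DataFrame([[0.5, 0.5, 0.0, 0.0]], index=["r"],
                           columns=[f"c{i}" for i in range(4)])
        labels = ["t1", "t1", "t2", "t2"]
        res = compute_rss(act, labels)
        assert res.query("cell_type == 't1'")["rss"].iloc[0] == pytest.approx(1.0)

    def test_disjoint_support_scores_zero(self):
        act = pd.DataFrame([[0.0, 0.0, 0.3, 0.7]], index=["r"],
                           columns=[f"c{i}" for i in range(4)])
        res = compute_rss(act, ["t1", "t1", "t2", "t2"])
        assert res.query("cell_type == 't1'")["rss"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_activity_vs_half_support_matches_analytic_jsd(self):
        """Closed form: p uniform over n cells, q uniform over n/2 cells."""
        n = 8
        act = pd.DataFrame([np.full(n, 1.0 / n)], index=["r"],
                           columns=[f"c{i}" for i in range(n)])
        labels = ["t1"] * (n // 2) + ["t2"] * (n // 2)
        # analytic base-2 JSD: inside cells p=1/n, q=2/n, m=3/(2n);
        # outside cells p=1/n, q=0, m=1/(2n)
        inside = n // 2
        kl_p_m = inside * (1 / n) * math.log2((1 / n) / (3 / (2 * n))) + \
            inside * (1 / n) * math.log2((1 / n) / (1 / (2 * n)))
        kl_q_m = inside * (2 / n) * math.log2((2 / n) / (3 / (2 * n)))
        jsd = 0.5 * kl_p_m + 0.5 * kl_q_m
        want = 1.0 - math.sqrt(jsd)
        res = compute_rss(act, labels)
        assert res.query("cell_type == 't1'")["rss"].iloc[0] == pytest.approx(want, abs=1e-12)

    def test_zero_activity_row_flagged(self):
        act = pd.DataFrame([[0.0, 0.0], [0.1, 0.9]], index=["dead", "live"],
                           columns=["c1", "c2"])
        res = compute_rss(act, ["t1", "t2"])
        assert res.query("regulon == 'dead'")["undefined"].all()
        assert not res.query("regulon == 'live'")["undefined"].any()

    def test_significance_needs_both_thresholds(self):
        rng = np.random.default_rng(2)
        act = pd.DataFrame(rng.random((5, 40)) * 0.05, index=list("abcde"))
        act.iloc[0, :20] = 0.5  # specific and strong
        labels = ["t1"] * 20 + ["t2"] * 20
        res = compute_rss(act, labels, aucell_min=0.1, rssz_min=1.0)
        hit = res.query("regulon == 'a' and cell_type == 't1'").iloc[0]
        assert hit["significant"]
        weak = res.query("regulon == 'b' and cell_type == 't1'").iloc[0]
        assert not weak["significant"]  # mean AUCell below 0.1


class TestCSI:
    # a written-out 5-regulon PCC matrix
    PCC = np.array(
        [
            [1.00, 0.90, 0.10, 0.20, 0.30],
            [0.90, 1.00, 0.15, 0.25, 0.05],
            [0.10, 0.15, 1.00, 0.85, 0.40],
            [0.20, 0.25, 0.85, 1.00, 0.35],
            [0.30, 0.05, 0.40, 0.35, 1.00],
        ]
    )

    def brute_force_csi(self, pcc):
        n = len(pcc)
        out = np.eye(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                count = 0
                for c in range(n):
                    if c in (i, j):
                        continue
                    if pcc[i, c] < pcc[i, j] and pcc[j, c] < pcc[i, j]:
                        count += 1
                out[i, j] = count / (n - 2)
        return out

    def test_matches_exhaustive_counting(self):
        got = csi_from_pcc(self.PCC)
        np.testing.assert_allclose(got, self.brute_force_csi(self.PCC), atol=1e-12)

    def test_dominant_pair_scores_one_dominated_zero(self):
        got = csi_from_pcc(self.PCC)
        assert got[0, 1] == 1.0  # 0.9 beats every other PCC of rows 0 and 1
        assert got[1, 4] == 0.0  # 0.05 beats nothing

    def test_random_matrices_symmetric_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            act = rng.random((6, 25))
            csi = compute_csi(pd.DataFrame(act, index=[f"r{i}" for i in range(6)]))
            v = csi.to_numpy()
            assert np.allclose(v, v.T)
            assert (v >= 0).all() and (v <= 1).all()
            assert np.allclose(np.diag(v), 1.0)

    def test_invariant_under_regulon_reordering(self):
        rng = np.random.default_rng(10)
        act = pd.DataFrame(rng.random((6, 30)), index=[f"r{i}" for i in range(6)])
        csi = compute_csi(act)
        perm = ["r3", "r0", "r5", "r1", "r4", "r2"]
        csi_p = compute_csi(act.loc[perm])
        np.testing.assert_allclose(csi.loc[perm, perm].to_numpy(), csi_p.to_numpy(), atol=1e-12)

    def test_zero_variance_regulon_excluded(self):
        act = pd.DataFrame(
            np.vstack([np.random.default_rng(3).random((3, 10)), np.full(10, 0.5)]),
            index=["a", "b", "c", "flat"],
        )
        with pytest.warns(UserWarning, match="zero variance"):
            csi = compute_csi(act)
        assert "flat" not in csi.index


class TestModules:
    def _block_csi(self, within=0.95, between=0.1):
        names = [f"r{i}" for i in range(6)]
        m = np.full((6, 6), between)
        m[:3, :3] = within
        m[3:, 3:] = within
        np.fill_diagonal(m, 1.0)
        return pd.DataFrame(m, index=names, columns=names)

    def test_separable_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        res = detect_modules(self._block_csi(), k=2, csi_min=0.8)
        truth = [0, 0, 0, 1, 1, 1]
        got = [res.modules[f"r{i}"] for i in range(6)]
        assert adjusted_rand_score(truth, got) == 1.0

    def test_k_one_puts_all_in_one_module(self):
        res = detect_modules(self._block_csi(), k=1, csi_min=0.8)
        assert set(res.modules.values()) == {1}

    def test_weak_regulons_unclustered(self):
        csi = self._block_csi(between=0.1)
        csi.iloc[5, :] = 0.1
        csi.iloc[:, 5] = 0.1
        csi.iloc[5, 5] = 1.0
        res = detect_modules(csi, k=2, csi_min=0.8)
        assert res.unclustered == ["r5"]

    def test_nothing_above_threshold_warns_empty(self):
        with pytest.warns(UserWarning, match="no CSI"):
            res = detect_modules(self._block_csi(within=0.5, between=0.1), k=2)
        assert res.modules == {}


class TestImportance:
    def _adata(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(200, 6))
        x[:, 3] = x[:, 0]                      # t1 copies regulator g1
        x[:, 4] = 0.9 * x[:, 1] + 0.1 * rng.normal(size=200)
        return _expr_adata(x, gene_ids=["g1", "g2", "g3", "t1", "t2", "t3"])

    @pytest.mark.parametrize("estimator", ["correlation", "tree_ensemble"])
    def test_copied_regulator_has_maximal_importance(self, estimator):
        im = infer_importance(
            self._adata(), ["g1", "g2", "g3"], ["t1", "t2", "t3"],
            estimator=estimator, seed=1, n_estimators=30,
        )
        t1 = im[im["target"] == "t1"].set_index("regulator")["importance"]
        assert t1.idxmax() == "g1"
        t2 = im[im["target"] == "t2"].set_index("regulator")["importance"]
        assert t2.idxmax() == "g2"

    def test_linear_network_top1_recovery(self):
        rng = np.random.default_rng(8)
        n = 300
        regs = rng.normal(size=(n, 3))
        correct = 0
        targets = []
        for j in range(10):
            driver = j % 3
            targets.append(regs[:, driver] * 1.0 + 0.4 * rng.normal(size=n))
        x = np.column_stack([regs, np.column_stack(targets)])
        ids = ["R1", "R2", "R3"] + [f"T{j}" for j in range(10)]
        im = infer_importance(_expr_adata(x, gene_ids=ids), ["R1", "R2", "R3"],
                              [f"T{j}" for j in range(10)], estimator="correlation")
        for j in range(10):
            best = im[im["target"] == f"T{j}"].set_index("regulator")["importance"].idxmax()
            correct += best == f"R{j % 3 + 1}"
        assert correct >= 9

    def test_noise_target_importance_near_zero(self):
        rng = np.random.default_rng(12)
        planted, noise = [], []
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 200
            reg = r.normal(size=n)
            x = np.column_stack([reg, reg + 0.3 * r.normal(size=n), r.normal(size=n)])
            im = infer_importance(_expr_adata(x, gene_ids=["R", "Tp", "Tn"]),
                                  ["R"], ["Tp", "Tn"], estimator="correlation")
            planted.append(im.query("target == 'Tp'")["importance"].iloc[0])
            noise.append(im.query("target == 'Tn'")["importance"].iloc[0])
        assert max(noise) < np.percentile(planted, 5)

    def test_extract_targets_strict_threshold(self):
        im = pd.DataFrame(
            {"regulator": ["R"] * 3, "target": ["a", "b", "c"],
             "importance": [1.2, 1.0, 0.3]}
        )
        assert extract_targets(im, "R", im_min=1.0) == ["a"]
        assert extract_targets(im, "R", im_min=0.0) == ["a", "b", "c"]
        assert extract_targets(im, "R", im_min=5.0) == []
        with pytest.raises(ConfigurationError):
            extract_targets(im, "unknown")
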