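"""QC filtering, normalization, HVG selection and marker annotation."""

import numpy as np
import pandas as pd
import pytest

from crossova.exceptions import ConfigurationError, EmptyResultError
from crossova.qc import annotate_by_markers, filter_cells_genes, normalize_log, select_hvg

from conftest import make_adata

# 6 cells x 10 genes; genes g1, g2 are mitochondrial (MT- symbols).
FIXTURE_COUNTS = np.array(
    [
        [5, 0, 3, 2, 1, 4, 0, 2, 1, 3],   # 8 genes detected, mito 5/21
        [0, 0, 1, 1, 1, 1, 1, 0, 0, 0],   # 5 genes, no mito
        [1, 1, 2, 2, 2, 2, 2, 2, 2, 2],   # 10 genes, mito 2/18
        [9, 9, 0, 0, 0, 1, 0, 0, 0, 0],   # 3 genes, mito 18/19
        [0, 0, 4, 4, 4, 4, 4, 4, 4, 4],   # 8 genes, no mito
        [0, 1, 0, 0, 0, 3, 3, 3, 3, 3],   # 6 genes, mito 1/16
    ]
)
MT_SYMBOLS = ["MT-g1", "MT-g2"] + [f"g{j}" for j in range(3, 11)]


def fixture_adata():
    adata = make_adata(FIXTURE_COUNTS)
    adata.var["symbol"] = MT_SYMBOLS
    return adata


def brute_force_filter(counts, symbols, min_genes, max_mito, min_cells):
    """Independent rule application: cells first, then genes."""
    keep_cells = []
    for i, row in enumerate(counts):
        detected = sum(1 for v in row if v > 0)
        mito = sum(v for v, s in zip(row, symbols) if s.upper().startswith("MT-"))
        frac = mito / sum(row) if sum(row) else 0.0
        if detected >= min_genes and frac <= max_mito:
            keep_cells.append(i)
    keep_genes = []
    for j in range(counts.shape[1]):
        n_detected = sum(1 for i in keep_cells if counts[i, j] > 0)
        if n_detected >= min_cells:
            keep_genes.append(j)
    return keep_cells, keep_genes


class TestFilterCellsGenes:
    @pytest.mark.parametrize(
        "min_genes,max_mito,min_cells", [(5, 0.10, 3), (6, 0.25, 2), (1, 1.0, 1), (8, 0.30, 4)]
    )
    def test_matches_exhaustive_rule_application(self, min_genes, max_mito, min_cells):
        adata = fixture_adata()
        out = filter_cells_genes(adata, min_genes, max_mito, min_cells)
        cells, genes = brute_force_filter(
            FIXTURE_COUNTS, MT_SYMBOLS, min_genes, max_mito, min_cells
        )
        assert list(out.obs_names) == [f"c{i + 1}" for i in cells]
        assert list(out.var_names) == [f"g{j + 1}" for j in genes]

    def test_boundary_convention(self):
        """A cell at exactly min_genes detected and exactly the mito bound stays."""
        counts = np.zeros((3, 250), dtype=int)
        counts[0, :199] = 1          # 199 genes -> removed
        counts[1, :200] = 1          # 200 genes, 10% mito -> retained
        counts[1, 200:220] = 0
        counts[2, :240] = 1          # kept companion
        adata = make_adata(counts)
        symbols = [f"MT-g{j}" if j < 20 else f"g{j}" for j in range(250)]
        adata.var["symbol"] = symbols
        # cell 2: 200 detected, mito = 20/200 = 0.10 exactly
        out = filter_cells_genes(adata, min_genes=200, max_mito=0.10, min_cells_per_gene=0)
        assert "c1" not in out.obs_names
        assert "c2" in out.obs_names

    def test_no_mito_genes_is_vacuous(self):
        adata = make_adata(FIXTURE_COUNTS)  # default symbols: no MT- prefix
        out = filter_cells_genes(adata, min_genes=0, max_mito=0.0, min_cells_per_gene=0)
        assert out.n_obs == 6

    def test_all_cells_removed_raises(self):
        with pytest.raises(EmptyResultError):
            filter_cells_genes(fixture_adata(), min_genes=100)

    def test_idempotent(self, two_species_dataset):
        adata = two_species_dataset.adatas["spA"]
        once = filter_cells_genes(adata, 50, 0.10, 3)
        twice = filter_cells_genes(once, 50, 0.10, 3)
        assert list(once.obs_names) == list(twice.obs_names)
        assert list(once.var_names) == list(twice.var_names)
        assert (once.X != twice.X).nnz == 0


class TestNormalizeLog:
    def test_formula(self):
        counts = np.array([[10, 90, 0], [1, 1, 2]])
        norm = normalize_log(make_adata(counts), scale_factor=1e4)
        x = np.asarray(norm.X.todense())
        assert x[0, 0] == pytest.approx(np.log1p(10 / 100 * 1e4))
        assert x[0, 2] == 0.0
        assert x[1, 2] == pytest.approx(np.log1p(2 / 4 * 1e4))

    def test_depth_invariance(self):
        counts = np.array([[3, 5, 7], [6, 10, 14]])
        norm = normalize_log(make_adata(counts))
        x = np.asarray(norm.X.todense())
        np.testing.assert_allclose(x[0], x[1], rtol=1e-12)

    def test_preserves_within_cell_ranks(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(3, size=(5, 40))
        norm = normalize_log(make_adata(counts))
        x = np.asarray(norm.X.todense())
        for i in range(5):
            assert np.array_equal(np.argsort(counts[i], kind="stable"),
                                  np.argsort(x[i], kind="stable"))

    def test_zero_total_cell_named_in_error(self):
        counts = np.array([[1, 2], [0, 0]])
        with pytest.raises(EmptyResultError, match="c2"):
            normalize_log(make_adata(counts))


class TestSelectHVG:
    def _random_norm(self, seed=0, n=80, g=40):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(0, 1, size=g)
        counts = rng.poisson(mu, size=(n, g))
        counts[:, 0] = 2  # constant gene; also guarantees nonzero cell totals
        return normalize_log(make_adata(counts))

    def test_constant_gene_never_selected(self):
        table = select_hvg(self._random_norm(), n_top=10)
        row = table[table["gene_id"] == "g1"].iloc[0]
        assert row["standardized_variance"] == 0.0
        assert not row["highly_variable"]

    def test_equal_mean_double_variance_ranks_higher(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(10, size=(400, 30))
        lo = rng.normal(10, 1, size=400).clip(0).round()
        hi = rng.normal(10, 3, size=400).clip(0).round()
        counts = np.column_stack([base, lo, hi]).astype(int)
        table = select_hvg(normalize_log(make_adata(counts)), n_top=5)
        r_lo = table.loc[table["gene_id"] == "g31", "rank"].iloc[0]
        r_hi = table.loc[table["gene_id"] == "g32", "rank"].iloc[0]
        assert r_hi < r_lo

    def test_invariant_to_gene_permutation(self):
        adata = self._random_norm(seed=2)
        table = select_hvg(adata, n_top=10)
        perm = np.random.default_rng(3).permutation(adata.n_vars)
        shuffled = adata[:, perm].copy()
        table2 = select_hvg(shuffled, n_top=10)
        merged = table.set_index("gene_id").join(
            table2.set_index("gene_id"), rsuffix="_p"
        )
        np.testing.assert_allclose(
            merged["standardized_variance"], merged["standardized_variance_p"], rtol=1e-9
        )
        assert (merged["rank"] == merged["rank_p"]).all()

    def test_matches_independent_vst_recipe(self):
        """Re-derive the vst statistic step by step on a 20-gene fixture."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        adata = self._random_norm(seed=5, n=60, g=20)
        counts = np.asarray(adata.layers["counts"].todense(), dtype=float)
        n = counts.shape[0]
        mean = counts.mean(0)
        var = counts.var(0, ddof=1)
        mask = (mean > 0) & (var > 0)
        fitted = lowess(np.log10(var[mask]), np.log10(mean[mask]), frac=0.3,
                        return_sorted=False)
        esd = np.sqrt(10.0 ** fitted)
        expected = np.zeros(counts.shape[1])
        for k, j in enumerate(np.where(mask)[0]):
            z = np.minimum((counts[:, j] - mean[j]) / esd[k], np.sqrt(n))
            expected[j] = (z**2).sum() / (n - 1)
        table = select_hvg(adata, n_top=5)
        np.testing.assert_allclose(
            table["standardized_variance"].to_numpy(), expected, rtol=1e-9
        )

    def test_n_top_above_gene_count_warns_and_returns_all(self):
        with pytest.warns(UserWarning, match="exceeds"):
            table = select_hvg(self._random_norm(), n_top=1000)
        assert table["highly_variable"].all()
        assert sorted(table["rank"]) == list(range(1, len(table) + 1))


class TestAnnotateByMarkers:
    def _norm(self):
        counts = np.array(
            [
                [9, 9, 0, 0],
                [8, 7, 1, 0],
                [0, 0, 9, 9],
                [0, 1, 9, 8],
            ]
        )
        return normalize_log(make_adata(counts))

    def test_argmax_assignment(self):
        norm = self._norm()
        res = annotate_by_markers(
            norm, ["k1", "k1", "k2", "k2"],
            {"endothelial": ["g1", "g2"], "granulosa": ["g3", "g4"]},
        )
        assert res.loc["k1", "cell_type"] == "endothelial"
        assert res.loc["k2", "cell_type"] == "granulosa"
        assert not res["tie"].any()

    def test_tie_broken_lexicographically_and_flagged(self):
        counts = np.full((2, 2), 5)
        res = annotate_by_markers(
            normalize_log(make_adata(counts)), ["k", "k"],
            {"theca": ["g1"], "immune": ["g2"]},
        )
        assert res.loc["k", "cell_type"] == "immune"
        assert res.loc["k", "tie"]

    def test_missing_markers_dropped_with_warning(self):
        norm = self._norm()
        with pytest.warns(UserWarning, match="absent"):
            res = annotate_by_markers(
                norm, ["k1", "k1", "k2", "k2"],
                {"endothelial": ["g1", "VWF"], "granulosa": ["g3"]},
            )
        assert res.loc["k1", "cell_type"] == "endothelial"

    def test_empty_map_rejected(self):
        with pytest.raises(ConfigurationError):
            annotate_by_markers(self._norm(), ["k"] * 4, {})

    def test_planted_markers_annotate_all_types(self, two_species_dataset, normalized_pair):
        norm = normalized_pair["spA"]
        truth = two_species_dataset.ground_truth
        marker_map = {
            t: [f"spA_{g}" for g in genes]
            for t, genes in truth.conserved_markers.items()
        }
        res = annotate_by_markers(norm, norm.obs["cell_type"], marker_map)
        assert (res.index == res["cell_type"]).all()
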