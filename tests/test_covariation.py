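"""Spearman networks, module clustering, complex recovery, cell-size fits."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scpqb import covariation, synthetic
from scpqb.covariation import (
    CovariationResult,
    cell_size_fit,
    cluster_modules,
    complex_recovery,
    filter_correlated,
    normalize_cells,
    pairwise_spearman,
    read_gene_sets,
    write_gene_sets,
)
from scpqb.errors import DataError, InputError
from scpqb.report_io import AbundanceMatrix, pivot_matrix
from scpqb.synthetic import CellSpec, ComplexSpec, NoiseConfig


def _cells_matrix(values: pd.DataFrame, is_log2=False) -> AbundanceMatrix:
    meta = pd.DataFrame(
        {"load_pg": np.nan, "replicate": range(1, values.shape[1] + 1)},
        index=values.columns,
    )
    return AbundanceMatrix(values, meta, row_unit="protein", is_log2=is_log2)


def _brute_force_spearman(x, y):
    """Rank-based oracle on pairwise-complete observations, average ranks."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    both = ~(np.isnan(x) | np.isnan(y))
    if both.sum() < 2:
        return np.nan
    rx = stats.rankdata(x[both])
    ry = stats.rankdata(y[both])
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom) if denom else np.nan


class TestNormalizeCells:
    def test_scaled_twin_cells_identical_after_normalization(self):
        vals = pd.DataFrame(
            {"c1": [2.0, 8.0, 32.0], "c2": [4.0, 16.0, 64.0], "c3": [3.0, 9.0, 27.0]}
        )
        out = normalize_cells(_cells_matrix(vals))
        pd.testing.assert_series_equal(
            out.values["c1"], out.values["c2"], check_names=False
        )

    def test_idempotent_on_centered_matrix(self):
        vals = pd.DataFrame({"c1": [4.0, 8.0, 16.0], "c2": [2.0, 4.0, 8.0], "c3": [1.0, 2.0, 4.0]})
        once = normalize_cells(_cells_matrix(vals))
        twice = normalize_cells(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_per_cell_median_zero_despite_size_factors(self, small_catalog):
        cells = synthetic.make_cell_specs(6, seed=3)
        rep, _ = synthetic.simulate_single_cells(small_catalog, cells, [], NoiseConfig(seed=3))
        m = normalize_cells(pivot_matrix(rep, row_unit="protein"))
        np.testing.assert_allclose(m.values.median(axis=0), 0.0, atol=1e-12)


class TestPairwiseSpearman:
    def test_monotone_pair_is_plus_one(self):
        vals = pd.DataFrame({"c1": [1.0, 10.0], "c2": [2.0, 20.0], "c3": [3.0, 25.0]},
                            index=["pA", "pB"])
        r = pairwise_spearman(_cells_matrix(vals), min_obs=2)
        assert r.rho.loc["pA", "pB"] == pytest.approx(1.0)

    def test_reversed_ranks_is_minus_one(self):
        vals = pd.DataFrame({"c1": [1.0, 30.0], "c2": [2.0, 20.0], "c3": [3.0, 10.0]},
                            index=["pA", "pB"])
        r = pairwise_spearman(_cells_matrix(vals), min_obs=2)
        assert r.rho.loc["pA", "pB"] == pytest.approx(-1.0)

    def test_hand_checked_permutation_value(self):
        # ranks (1,2,3,4) vs (3,1,4,2): sum d^2 = 10 -> rho = 1 - 60/60 = 0
        assert _brute_force_spearman([1, 2, 3, 4], [3, 1, 4, 2]) == pytest.approx(0.0)
        vals = pd.DataFrame(
            {"c1": [1.0, 3.0], "c2": [2.0, 1.0], "c3": [3.0, 4.0], "c4": [4.0, 2.0]},
            index=["pA", "pB"],
        )
        r = pairwise_spearman(_cells_matrix(vals), min_obs=2)
        assert r.rho.loc["pA", "pB"] == pytest.approx(0.0)

    def test_matches_brute_force_oracle_with_ties_and_missing(self):
        rng = np.random.default_rng(41)
        raw = rng.integers(0, 6, size=(8, 10)).astype(float) + 1.0  # many ties
        raw[rng.random(raw.shape) < 0.2] = np.nan
        vals = pd.DataFrame(raw, index=[f"p{i}" for i in range(8)],
                            columns=[f"c{j}" for j in range(10)])
        r = pairwise_spearman(_cells_matrix(vals), min_obs=3)
        for i in range(8):
            for j in range(i + 1, 8):
                expected = _brute_force_spearman(raw[i], raw[j])
                got = r.rho.iloc[i, j]
                n = r.n_obs.iloc[i, j]
                if n < 3:
                    assert np.isnan(got)
                elif np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        raw = rng.lognormal(3, 1, size=(5, 12))
        vals = pd.DataFrame(raw, index=[f"p{i}" for i in range(5)],
                            columns=[f"c{j}" for j in range(12)])
        transformed = vals.copy()
        transformed.iloc[0] = np.exp(transformed.iloc[0] / transformed.iloc[0].max())
        a = pairwise_spearman(_cells_matrix(vals), min_obs=3).rho
        b = pairwise_spearman(_cells_matrix(transformed), min_obs=3).rho
        pd.testing.assert_frame_equal(a, b)

    def test_symmetry_and_unit_diagonal(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.lognormal(3, 1, size=(6, 15)))
        vals.index = [f"p{i}" for i in range(6)]
        vals.columns = [f"c{j}" for j in range(15)]
        r = pairwise_spearman(_cells_matrix(vals), min_obs=3)
        pd.testing.assert_frame_equal(r.rho, r.rho.T)
        assert np.allclose(np.diag(r.rho), 1.0)

    def test_fewer_than_three_cells_rejected(self):
        vals = pd.DataFrame({"c1": [1.0, 2.0], "c2": [2.0, 3.0]}, index=["pA", "pB"])
        with pytest.raises(InputError):
            pairwise_spearman(_cells_matrix(vals))


class TestFilterCorrelated:
    def _result(self):
        rho = pd.DataFrame(
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.2], [0.1, 0.2, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        n = pd.DataFrame(20, index=rho.index, columns=rho.columns)
        return CovariationResult(list(rho.index), rho, n)

    def test_threshold_zero_keeps_all(self):
        assert filter_correlated(self._result(), 0.0) == ["a", "b", "c"]

    def test_threshold_one_without_perfect_pairs_empty(self):
        assert filter_correlated(self._result(), 1.0) == []

    def test_default_threshold_keeps_correlated_pair(self):
        assert filter_correlated(self._result(), 0.6) == ["a", "b"]

    def test_monotone_non_increasing_in_threshold(self):
        res = self._result()
        sizes = [len(filter_correlated(res, t)) for t in (0.0, 0.3, 0.6, 0.95, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(InputError):
            filter_correlated(self._result(), 1.5)


class TestClusterModules:
    def _block_result(self):
        # two perfectly anti-correlated 2-blocks
        rho = pd.DataFrame(
            [
                [1.0, 1.0, -1.0, -1.0],
                [1.0, 1.0, -1.0, -1.0],
                [-1.0, -1.0, 1.0, 1.0],
                [-1.0, -1.0, 1.0, 1.0],
            ],
            index=list("abcd"), columns=list("abcd"),
        )
        n = pd.DataFrame(20, index=rho.index, columns=rho.columns)
        return CovariationResult(list(rho.index), rho, n)

    def test_anti_correlated_blocks_split_exactly(self):
        out = cluster_modules(self._block_result(), k=2)
        labels = out.module_label
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]

    def test_k_one_single_module(self):
        out = cluster_modules(self._block_result(), k=1)
        assert out.module_label.nunique() == 1

    def test_k_above_n_rejected(self):
        with pytest.raises(InputError):
            cluster_modules(self._block_result(), k=5)

    def test_deterministic_labels_and_leaf_order(self):
        a = cluster_modules(self._block_result(), k=2)
        b = cluster_modules(self._block_result(), k=2)
        pd.testing.assert_series_equal(a.module_label, b.module_label)
        assert a.leaf_order == b.leaf_order

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_simulated_complexes_coassigned(self, seed):
        cat = synthetic.simulate_catalog(120, (1, 2), 3.0, seed=seed)
        cells = synthetic.make_cell_specs(100, seed=seed)
        cxs = synthetic.make_complexes(cat, [6, 8], [0.9, 0.9], seed=seed)
        rep, _ = synthetic.simulate_single_cells(cat, cells, cxs, NoiseConfig(seed=seed))
        m = normalize_cells(pivot_matrix(rep, row_unit="protein"))
        result = pairwise_spearman(m, min_obs=10)
        out = cluster_modules(result, k=3)
        for cx in cxs:
            present = [p for p in cx.member_proteins if p in out.module_label.index]
            assert len(present) >= 2
            assert out.module_label[present].nunique() == 1


class TestComplexRecovery:
    def test_perfect_two_protein_complex_delta_one(self):
        rho = pd.DataFrame(
            [[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        n = pd.DataFrame(20, index=rho.index, columns=rho.columns)
        result = CovariationResult(list(rho.index), rho, n)
        out = complex_recovery(result, {"pair": ["a", "b"]}, n_perm=99, seed=0)
        assert out["delta"].iloc[0] == pytest.approx(1.0)

    def test_single_present_member_flagged_nan(self):
        rho = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=list("ab"), columns=list("ab"))
        n = pd.DataFrame(20, index=rho.index, columns=rho.columns)
        result = CovariationResult(list(rho.index), rho, n)
        out = complex_recovery(result, {"lonely": ["a", "zz"]}, n_perm=9, seed=0)
        assert np.isnan(out["delta"].iloc[0])
        assert out["n_members_present"].iloc[0] == 1

    def test_permutation_p_within_bounds_and_smoothed(self):
        rng = np.random.default_rng(10)
        raw = rng.normal(size=(12, 40))
        rho = pd.DataFrame(np.corrcoef(raw), index=[f"p{i}" for i in range(12)],
                           columns=[f"p{i}" for i in range(12)])
        n = pd.DataFrame(40, index=rho.index, columns=rho.columns)
        result = CovariationResult(list(rho.index), rho, n)
        out = complex_recovery(result, {"x": ["p0", "p1", "p2"]}, n_perm=99, seed=1)
        p = out["permutation_p"].iloc[0]
        assert 1 / 100 <= p <= 1.0


class TestCellSizeFit:
    def _exact_linear(self):
        fsc = np.array([600.0, 800.0, 1000.0, 1200.0, 1400.0])
        cells = [f"c{i}" for i in range(5)]
        # one shared peptide whose log2 intensity is linear in fsc
        intensities = 2.0 ** (0.002 * fsc + 3.0)
        vals = pd.DataFrame([intensities, intensities * 2], index=["pA", "pB"], columns=cells)
        meta = pd.DataFrame({"load_pg": np.nan, "replicate": range(1, 6)}, index=cells)
        matrix = AbundanceMatrix(vals, meta)
        cell_meta = pd.DataFrame({"cell_id": cells, "fsc_a": fsc})
        return matrix, cell_meta

    def test_exact_linear_recovered_with_r_one(self):
        matrix, meta = self._exact_linear()
        fit = cell_size_fit(matrix, meta)
        assert fit.ok
        assert fit.slope == pytest.approx(0.002, rel=1e-9)
        assert fit.r == pytest.approx(1.0)

    def test_constant_fsc_flagged_undefined(self):
        matrix, meta = self._exact_linear()
        meta["fsc_a"] = 1000.0
        fit = cell_size_fit(matrix, meta)
        assert not fit.ok and np.isnan(fit.slope)

    def test_permuted_fsc_labels_give_near_zero_slope(self, small_catalog):
        cells = synthetic.make_cell_specs(60, seed=5)
        rep, meta = synthetic.simulate_single_cells(small_catalog, cells, [], NoiseConfig(seed=5))
        m = pivot_matrix(rep)
        rng = np.random.default_rng(5)
        shuffled = meta.copy()
        shuffled["fsc_a"] = rng.permutation(shuffled["fsc_a"].to_numpy())
        true_slope = synthetic.true_size_slope(cells, NoiseConfig())
        fit = cell_size_fit(m, shuffled)
        assert abs(fit.slope) < 0.3 * abs(true_slope)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_recovers_generator_slope_within_ten_percent(self, seed):
        cat = synthetic.simulate_catalog(300, (1, 2), 3.0, seed=seed)
        cells = synthetic.make_cell_specs(100, seed=seed)
        cfg = NoiseConfig(seed=seed)
        rep, meta = synthetic.simulate_single_cells(cat, cells, [], cfg)
        fit = cell_size_fit(pivot_matrix(rep), meta)
        truth = synthetic.true_size_slope(cells, cfg)
        assert fit.slope == pytest.approx(truth, rel=0.10)

    def test_protein_group_counts_attached(self, small_catalog):
        cells = synthetic.make_cell_specs(5, seed=9)
        rep, meta = synthetic.simulate_single_cells(small_catalog, cells, [], NoiseConfig(seed=9))
        protein_of = dict(rep[["peptide_id", "protein_id"]].drop_duplicates().to_numpy())
        fit = cell_size_fit(pivot_matrix(rep), meta, protein_of=protein_of)
        assert (fit.per_cell["n_protein_groups"] >= 1).all()
        assert (fit.per_cell["n_protein_groups"] <= small_catalog["protein_id"].nunique()).all()


class TestGeneSetIO:
    def test_round_trip(self, tmp_path):
        sets = {"mcm": ["P1", "P2", "P3"], "proteasome": ["P4", "P5"]}
        path = str(tmp_path / "sets.gmt")
        write_gene_sets(sets, path)
        assert read_gene_sets(path) == sets

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("\n")
        with pytest.raises(DataError):
            read_gene_sets(str(path))
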