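import numpy as np
import pandas as pd
import pytest

from aspen.core import (
    AspenConfig,
    PseudobulkMeans,
    apply_dual_gate,
    eligible_celltypes,
    gene_age_correlation,
    module_scores,
    pseudobulk_means,
    run_aspen,
    score_age_correlation,
)
from aspen.datasets import GeneSetCollection, lognormalize
from aspen.synthgen import CohortConfig, PlantedProgram, simulate_cohort


def _cells(donor_types: dict[str, list[str]]) -> pd.DataFrame:
    rows = []
    for donor, types in donor_types.items():
        for i, ct in enumerate(types):
            rows.append(dict(barcode=f"{donor}_{i}", donor_id=donor,
                             celltype_major="M", celltype_minor=ct))
    return pd.DataFrame(rows)


def _donors(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        dict(age=np.linspace(40, 70, n), subtype="TNBC"),
        index=pd.Index([f"D{i}" for i in range(n)], name="donor_id"),
    )


class TestEligibility:
    def test_exactly_half_is_retained(self):
        donors = _donors(10)
        cells = _cells({f"D{i}": ["T"] for i in range(5)})
        kept, excluded = eligible_celltypes(cells, donors)
        assert "T" in kept and len(kept["T"]) == 5 and excluded.empty

    def test_below_half_is_excluded_with_reason(self):
        donors = _donors(10)
        cells = _cells({f"D{i}": ["T"] for i in range(4)})
        kept, excluded = eligible_celltypes(cells, donors)
        assert "T" not in kept
        assert excluded.iloc[0]["cell_type"] == "T"
        assert "4/10" in excluded.iloc[0]["reason"]

    def test_donor_excluded_per_type_not_globally(self):
        donors = _donors(4)
        cells = _cells({"D0": ["A", "B"], "D1": ["A", "B"], "D2": ["A", "B"], "D3": ["A"]})
        kept, _ = eligible_celltypes(cells, donors)
        assert kept["A"] == ["D0", "D1", "D2", "D3"]
        assert kept["B"] == ["D0", "D1", "D2"]

    def test_two_donor_minimum(self):
        with pytest.raises(ValueError):
            eligible_celltypes(_cells({"D0": ["T"]}), _donors(1))


class TestPseudobulk:
    def test_donor_mean_is_arithmetic(self, toy_lognorm):
        pb = pseudobulk_means(toy_lognorm, "iCAF", ["D3"])
        expected = toy_lognorm.lognorm_matrix()[4:6].mean(axis=0)
        np.testing.assert_allclose(pb.expr["D3"], np.asarray(expected).ravel())

    def test_single_cell_donor_column_is_profile(self, toy_lognorm):
        pb = pseudobulk_means(toy_lognorm, "CD4", ["D1", "D2"])
        np.testing.assert_allclose(
            pb.expr["D1"], toy_lognorm.lognorm_matrix()[0].toarray().ravel()
        )

    def test_empty_donor_list_raises(self, toy_lognorm):
        with pytest.raises(ValueError):
            pseudobulk_means(toy_lognorm, "CD4", [])


class TestAgeCorrelationRanking:
    def _pb(self, matrix, ages=(40.0, 50.0, 60.0), genes=None):
        genes = genes or [f"g{i}" for i in range(len(matrix))]
        expr = pd.DataFrame(matrix, index=genes, columns=["D1", "D2", "D3"])
        return PseudobulkMeans("ct", expr, np.array(ages))

    def test_perfect_and_hand_derived_correlations(self):
        ranking = gene_age_correlation(self._pb([[1, 2, 3], [1, 3, 2]]))
        assert ranking.genes == ["g0", "g1"]
        assert ranking.stats == pytest.approx([1.0, 0.5])

    def test_zero_variance_goes_to_ledger(self):
        ranking = gene_age_correlation(self._pb([[1, 2, 3], [2, 2, 2]]))
        assert ranking.genes == ["g0"]
        assert ranking.dropped.iloc[0]["reason"] == "zero-variance"

    def test_ties_break_lexicographically(self):
        ranking = gene_age_correlation(
            self._pb([[1, 2, 3], [2, 4, 6]], genes=["zz", "aa"])
        )
        assert ranking.genes == ["aa", "zz"]

    def test_sorted_strictly_nonincreasing_without_zeros(self):
        rng = np.random.default_rng(0)
        ranking = gene_age_correlation(self._pb(rng.normal(size=(50, 3))))
        assert np.all(np.diff(ranking.stats) <= 0)
        assert np.all(np.abs(ranking.stats) > 0)
        assert np.all(np.abs(ranking.stats) <= 1.0 + 1e-12)

    def test_too_few_donors_raises(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g0"], columns=["D1", "D2"])
        with pytest.raises(ValueError):
            gene_age_correlation(PseudobulkMeans("ct", expr, np.array([40.0, 50.0])))


class TestModuleScores:
    def test_uniform_expression_scores_zero(self, toy_dataset, small_sets):
        toy_dataset.adata.layers["lognorm"] = np.ones((6, 4))
        ms = module_scores(toy_dataset, small_sets, n_bins=1, n_ctrl=10, seed=0)
        np.testing.assert_allclose(ms.scores.to_numpy(), 0.0, atol=1e-15)

    def test_single_bin_constant_offset(self, toy_dataset):
        layer = np.ones((6, 4))
        layer[:, 0] = 2.0  # signature gene GA constant at 2, everything else at 1
        toy_dataset.adata.layers["lognorm"] = layer
        sets = GeneSetCollection({"S": ["GA"]})
        ms = module_scores(toy_dataset, sets, n_bins=1, n_ctrl=10, seed=0,
                           exclude_signature=True)
        np.testing.assert_allclose(ms.scores["S"], 1.0)

    def test_same_seed_bitwise_identical(self, toy_lognorm, small_sets):
        a = module_scores(toy_lognorm, small_sets, n_bins=2, n_ctrl=2, seed=3)
        b = module_scores(toy_lognorm, small_sets, n_bins=2, n_ctrl=2, seed=3)
        np.testing.assert_array_equal(a.scores.to_numpy(), b.scores.to_numpy())

    def test_shift_of_signature_genes_shifts_score(self):
        # with a single bin and controls excluding signature genes, adding a
        # constant to the signature genes' expression shifts scores by exactly it
        ds, sets, _ = simulate_cohort(CohortConfig(n_donors=3, n_genes=200, n_sets=2,
                                                   set_size=10, seed=0))
        lognormalize(ds)
        ref = module_scores(ds, sets, n_bins=1, n_ctrl=200, seed=1,
                            exclude_signature=True)
        layer = ds.adata.layers["lognorm"].toarray()
        sig_idx = [ds.gene_ids.index(g) for g in sets["SET_1"]]
        layer[:, sig_idx] += 0.7
        ds.adata.layers["lognorm"] = layer
        shifted = module_scores(ds, sets, n_bins=1, n_ctrl=200, seed=1,
                                exclude_signature=True)
        np.testing.assert_allclose(
            shifted.scores["SET_1"].to_numpy() - ref.scores["SET_1"].to_numpy(),
            0.7, atol=1e-9,
        )

    def test_unmatched_set_flagged_not_scored(self, toy_lognorm):
        sets = GeneSetCollection({"S": ["NOPE"]})
        ms = module_scores(toy_lognorm, sets, n_bins=1, n_ctrl=2, seed=0)
        assert "S" in ms.not_scored and ms.scores["S"].isna().all()

    def test_too_many_bins_raises(self, toy_lognorm, small_sets):
        with pytest.raises(ValueError):
            module_scores(toy_lognorm, small_sets, n_bins=10, n_ctrl=2, seed=0)


class TestScoreAgeCorrelation:
    def _run(self, means_by_donor):
        scores = pd.DataFrame({"S": np.concatenate(list(means_by_donor.values()))})
        scores.index = [f"c{i}" for i in range(len(scores))]
        cells = pd.DataFrame(
            dict(
                donor_id=np.repeat(list(means_by_donor), [len(v) for v in means_by_donor.values()]),
                celltype_minor="T",
            ),
            index=scores.index,
        )
        donors = pd.DataFrame(
            dict(age=[40.0, 50.0, 60.0]), index=pd.Index(["D1", "D2", "D3"], name="donor_id")
        )
        from aspen.core import ModuleScoreMatrix

        ms = ModuleScoreMatrix(scores=scores, bins=pd.Series(dtype=int), seed=0)
        return score_age_correlation(ms, cells, donors, {"T": ["D1", "D2", "D3"]})

    def test_increasing_scores_give_positive_r(self):
        out = self._run({"D1": [0.1, 0.1], "D2": [0.2], "D3": [0.3, 0.3]})
        assert out.iloc[0]["score_age_r"] == pytest.approx(1.0)

    def test_decreasing_scores_give_negative_r(self):
        out = self._run({"D1": [0.3], "D2": [0.2], "D3": [0.1]})
        assert out.iloc[0]["score_age_r"] == pytest.approx(-1.0)

    def test_constant_scores_flagged(self):
        out = self._run({"D1": [0.2], "D2": [0.2], "D3": [0.2]})
        assert not out.iloc[0]["score_age_defined"]


class TestDualGate:
    def test_gate_is_logical_and_of_both_arms(self):
        table = pd.DataFrame(
            dict(
                padj_perm=[0.01, 0.01, 0.20, 0.20],
                padj_param=[0.01, 0.20, 0.01, 0.20],
                nes=[1.0, -1.0, 2.0, np.nan],
            )
        )
        gated = apply_dual_gate(table, alpha=0.05)
        assert gated["significant"].tolist() == [True, False, False, False]
        assert gated["direction"].tolist() == ["older", "younger", "older", ""]


@pytest.fixture(scope="module")
def planted_run():
    cfg = CohortConfig(planted=[PlantedProgram("cancer_basal", "SET_1", 0.65)], seed=7)
    dataset, sets, truth = simulate_cohort(cfg)
    result = run_aspen(dataset, sets, AspenConfig(n_permutations=500, seed=7))
    return result, truth


class TestRunAspen:
    def test_planted_program_detected_with_positive_direction(self, planted_run):
        result, truth = planted_run
        planted = truth.programs[0]
        row = result.table[
            (result.table["cell_type"] == planted["cell_type"])
            & (result.table["gene_set"] == planted["gene_set"])
        ].iloc[0]
        assert bool(row["significant"])
        assert row["nes"] > 0 and row["direction"] == "older"
        assert row["score_age_r"] > 0

    def test_every_eligible_pair_appears_once(self, planted_run):
        result, _ = planted_run
        assert not result.table.duplicated(["cell_type", "gene_set"]).any()
        assert set(result.table["cell_type"].unique()) == {
            "CD4_T", "CD8_T", "cancer_basal", "cancer_cycling", "iCAF", "myCAF"
        }

    def test_rare_celltype_goes_to_ledger_not_table(self):
        from aspen.synthgen import CellTypeSpec, default_cell_types

        cfg = CohortConfig(seed=3, n_genes=300, n_sets=2, set_size=20)
        cfg.cell_types = default_cell_types()[:2] + [CellTypeSpec("rare", "M", 0.4)]
        dataset, sets, _ = simulate_cohort(cfg)
        if "rare" not in set(dataset.cells["celltype_minor"]):
            pytest.skip("no rare cells drawn at this seed")
        result = run_aspen(dataset, sets, AspenConfig(n_permutations=100, seed=3))
        present = dataset.cells.groupby("celltype_minor", observed=True)["donor_id"].nunique()
        if present["rare"] / len(dataset.donors) < 0.5:
            assert "rare" not in set(result.table["cell_type"])
            assert "rare" in set(result.excluded["cell_type"])
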