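import numpy as np
import pandas as pd
import pytest

from aspen.interactome import (
    aggregate_strengths,
    classify_nodes,
    pathway_mean_probabilities,
    pathway_regressions,
    prioritize_pathways,
    run_interactome,
    select_cell_types,
)
from aspen.synthgen import InteractionBias, InteractionConfig, simulate_interactions


def _records(rows):
    return pd.DataFrame(
        rows, columns=["cohort", "source", "target", "pathway", "lr_pair", "prob", "pval"]
    )


class TestStrengths:
    def test_source_strength_sums_probabilities(self):
        rec = _records([
            ("young", "A", "B", "P", "L_R", 0.1, 0.5),
            ("young", "A", "C", "P", "L_R", 0.2, 0.5),
        ])
        s = aggregate_strengths(rec).set_index(["cell_type", "role", "cohort"])
        assert s.loc[("A", "source", "young"), "strength"] == pytest.approx(0.3)

    def test_absent_combination_is_zero(self):
        rec = _records([("young", "A", "B", "P", "L_R", 0.1, 0.5)])
        s = aggregate_strengths(rec).set_index(["cell_type", "role", "cohort"])
        assert s.loc[("B", "source", "old"), "strength"] == 0.0

    def test_homotypic_counts_both_roles(self):
        rec = _records([("old", "A", "A", "P", "L_R", 0.4, 0.5)])
        s = aggregate_strengths(rec).set_index(["cell_type", "role", "cohort"])
        assert s.loc[("A", "source", "old"), "strength"] == pytest.approx(0.4)
        assert s.loc[("A", "target", "old"), "strength"] == pytest.approx(0.4)

    def test_matches_bruteforce_sums_on_random_table(self):
        rng = np.random.default_rng(3)
        rows = [
            (rng.choice(["young", "old"]), f"T{rng.integers(4)}", f"T{rng.integers(4)}",
             "P", "L_R", float(rng.random()), 0.5)
            for _ in range(200)
        ]
        rec = _records(rows)
        s = aggregate_strengths(rec).set_index(["cell_type", "role", "cohort"])
        for ct in rec["source"].unique():
            for cohort in ("young", "old"):
                manual = rec[(rec["source"] == ct) & (rec["cohort"] == cohort)]["prob"].sum()
                assert s.loc[(ct, "source", cohort), "strength"] == pytest.approx(manual)


class TestSelection:
    def _strengths(self, young, old):
        rows = []
        for ct, v in young.items():
            rows.append(dict(cell_type=ct, role="source", cohort="young", strength=v))
            rows.append(dict(cell_type=ct, role="target", cohort="young", strength=0.0))
        for ct, v in old.items():
            rows.append(dict(cell_type=ct, role="source", cohort="old", strength=v))
            rows.append(dict(cell_type=ct, role="target", cohort="old", strength=0.0))
        return pd.DataFrame(rows)

    def test_worked_threshold_example(self):
        sel = select_cell_types(self._strengths({"A": 2.0, "B": 0.1}, {"A": 1.7, "B": 0.1}))
        assert sel.thresholds["source"] == pytest.approx(1.95)
        assert sel.selected == ["A"]

    def test_equal_strengths_select_nothing(self):
        sel = select_cell_types(self._strengths({"A": 1.0, "B": 1.0}, {"A": 1.0, "B": 1.0}))
        assert sel.selected == []

    def test_manual_exclusion_recorded(self):
        sel = select_cell_types(
            self._strengths({"A": 2.0, "B": 0.1}, {"A": 1.7, "B": 0.1}),
            manual_exclusions={"A": "subtype unknown"},
        )
        assert sel.selected == []
        assert sel.excluded_manually.iloc[0]["cell_type"] == "A"
        assert sel.excluded_manually.iloc[0]["reason"] == "subtype unknown"

    def test_single_cohort_rejected(self):
        s = self._strengths({"A": 1.0}, {})
        s = s[s["cohort"] == "young"]
        with pytest.raises(ValueError, match="old"):
            select_cell_types(s)


class TestPathwayMeans:
    def test_mean_over_lr_pairs(self):
        rec = _records([
            ("young", "A", "B", "P", "L1_R1", 0.2, 0.5),
            ("young", "A", "B", "P", "L2_R2", 0.4, 0.5),
        ])
        out = pathway_mean_probabilities(rec, ["A", "B"])
        assert out.iloc[0]["mean_prob"] == pytest.approx(0.3)

    def test_unselected_types_dropped_and_missing_combo_absent(self):
        rec = _records([
            ("young", "A", "B", "P", "L1_R1", 0.2, 0.5),
            ("young", "C", "B", "P", "L1_R1", 0.9, 0.5),
        ])
        out = pathway_mean_probabilities(rec, ["A", "B"])
        assert len(out) == 1
        assert set(out["source"]) == {"A"}


class TestPrioritization:
    def _regs(self, p, freq):
        mean_probs = pd.DataFrame(
            dict(pathway="P", source="A", target="B", cohort=["young", "old"],
                 mean_prob=[0.1, 0.2])
        )
        regs = pathway_regressions(mean_probs)
        regs[0].p, regs[0].frequency, regs[0].testable = p, freq, True
        return regs

    @pytest.mark.parametrize(
        "p,freq,expected",
        [(0.03, 20, True), (0.03, 10, False), (0.20, 30, False)],
    )
    def test_threshold_combinations(self, p, freq, expected):
        out = prioritize_pathways(self._regs(p, freq))
        assert bool(out.iloc[0]["selected"]) is expected


class TestNodeClassification:
    def _node(self, p_young, p_old, prob_young, prob_old):
        rows = []
        if p_young is not None:
            rows.append(("young", "A", "B", "P", "L_R", prob_young, p_young))
        if p_old is not None:
            rows.append(("old", "A", "B", "P", "L_R", prob_old, p_old))
        return classify_nodes(_records(rows), ["P"])

    def test_exclusive_when_significant_in_one_cohort(self):
        out = self._node(0.5, 0.005, 0.05, 0.06)
        assert out.iloc[0]["classification"] == "older-exclusive"

    def test_biased_at_fold_1_2(self):
        out = self._node(0.005, 0.005, 0.05, 0.06)
        assert out.iloc[0]["fold_difference"] == pytest.approx(1.2)
        assert out.iloc[0]["classification"] == "older-biased"

    def test_shared_below_fold(self):
        out = self._node(0.005, 0.005, 0.05, 0.055)
        assert out.iloc[0]["classification"] == "shared"

    def test_absent_cohort_gives_exclusive_with_infinite_fold(self):
        out = self._node(None, 0.005, None, 0.06)
        assert out.iloc[0]["classification"] == "older-exclusive"
        assert np.isinf(out.iloc[0]["fold_difference"])

    def test_inactive_nodes_omitted(self):
        out = self._node(0.5, 0.5, 0.05, 0.06)
        assert out.empty

    def test_cohort_swap_flips_polarity(self):
        cfg = InteractionConfig(biases=[InteractionBias("PW_1", "old", 2.0)], seed=9)
        records, _ = simulate_interactions(cfg)
        swapped = records.copy()
        swapped["cohort"] = swapped["cohort"].map({"young": "old", "old": "young"})
        a = classify_nodes(records, ["PW_1"])
        b = classify_nodes(swapped, ["PW_1"])
        flip = {"older-exclusive": "younger-exclusive",
                "younger-exclusive": "older-exclusive",
                "older-biased": "younger-biased",
                "younger-biased": "older-biased",
                "shared": "shared"}
        merged = a.merge(b, on=["pathway", "lr_pair", "source", "target"])
        assert len(merged) == len(a) > 0
        assert (merged["classification_y"] == merged["classification_x"].map(flip)).all()


class TestRecovery:
    def test_planted_bias_recovered_single_seed(self):
        cfg = InteractionConfig(biases=[InteractionBias("PW_1", "old", 2.0)], seed=4)
        records, truth = simulate_interactions(cfg)
        selection, pathways, nodes = run_interactome(records)
        assert set(selection.selected) == set(cfg.cell_types)
        row = pathways.set_index("pathway").loc["PW_1"]
        assert bool(row["selected"]) and row["frequency"] >= 15
        called = nodes[nodes["pathway"] == "PW_1"]
        toward_old = called["classification"].isin(["older-exclusive", "older-biased"])
        assert toward_old.mean() >= 0.9
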