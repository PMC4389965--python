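import numpy as np
import pandas as pd
import pytest

from _reference import brute_force_regulated
from conftest import build_matrix, clone_effect

from evi1kit import (
    TimeCourseDesign,
    call_regulated,
    collapse_probesets,
    compute_fold_changes,
    filter_probesets,
    order_for_heatmap,
    run_filter,
    simulate_timecourse,
)
from evi1kit.timecourse import ConfigurationError


class TestIntensityFilter:
    def test_bright_probe_retained_dim_condition_drops(self):
        matrix = build_matrix(
            {
                "bright": {},
                "dim_in_one": {("E10", "plus", 24): 2.8, ("E10", "minus", 24): 3.0},
            }
        )
        # dim_in_one: mean 2.9 in E10 @ 24 h, >= 3 everywhere else
        assert filter_probesets(matrix) == ["bright"]

    def test_boundary_mean_exactly_three_is_retained(self):
        matrix = build_matrix(
            {"edge": {("P2", "plus", 48): 3.0, ("P2", "minus", 48): 3.0}}
        )
        assert filter_probesets(matrix) == ["edge"]

    def test_unannotated_probe_dropped(self):
        matrix = build_matrix(
            {"a": {}, "b": {}}, probe_to_gene={"a": "GENE1"}
        )
        assert filter_probesets(matrix) == ["a"]

    def test_planted_below_threshold_counted_per_probe(self):
        rng = np.random.default_rng(0)
        conds = {}
        conditions = [("E10", 24), ("E10", 48), ("E14", 24), ("E14", 48),
                      ("P2", 48), ("U937T", 48)]
        for i in range(100):
            probe = f"p{i:03d}"
            if i < 30:  # below threshold in exactly one condition
                line, h = conditions[int(rng.integers(len(conditions)))]
                conds[probe] = {(line, "plus", h): 2.0, (line, "minus", h): 2.0}
            else:
                conds[probe] = {}
        matrix = build_matrix(conds)
        assert len(filter_probesets(matrix)) == 70

    def test_missing_condition_is_a_configuration_error(self):
        matrix = build_matrix({"a": {}})
        broken = matrix.metadata[matrix.metadata.sample_id != "P2_minus_48h"]
        from evi1kit import TimeCourseMatrix

        m2 = TimeCourseMatrix(
            values=matrix.values[broken.sample_id],
            metadata=broken,
            probe_to_gene=matrix.probe_to_gene,
        )
        with pytest.raises(ConfigurationError, match="P2"):
            filter_probesets(m2)


class TestFoldChanges:
    def test_identical_tet_pairs_give_zero(self):
        matrix = build_matrix({"a": {}})
        assert (compute_fold_changes(matrix).to_numpy() == 0.0).all()

    def test_uniform_shift_gives_that_shift(self):
        matrix = build_matrix({"a": {}})
        minus_cols = matrix.metadata.loc[
            matrix.metadata.tet == "minus", "sample_id"
        ]
        matrix.values.loc["a", minus_cols] += 2.0
        assert (compute_fold_changes(matrix).loc["a"] == 2.0).all()

    def test_matches_elementwise_oracle_and_antisymmetry(self):
        rng = np.random.default_rng(7)
        matrix = build_matrix({f"p{i}": {} for i in range(20)})
        matrix.values.iloc[:, :] = rng.normal(8, 2, matrix.values.shape)
        fcs = compute_fold_changes(matrix)
        meta = matrix.metadata
        for probe in matrix.values.index:
            for line, h in {(r.cell_line, r.hours) for r in meta.itertuples()}:
                plus = meta[(meta.cell_line == line) & (meta.tet == "plus") & (meta.hours == h)].sample_id.iloc[0]
                minus = meta[(meta.cell_line == line) & (meta.tet == "minus") & (meta.hours == h)].sample_id.iloc[0]
                expected = matrix.values.loc[probe, minus] - matrix.values.loc[probe, plus]
                assert fcs.loc[probe, (line, h)] == expected

        # swapping tet labels flips every fold change
        swapped_meta = meta.assign(tet=meta.tet.map({"plus": "minus", "minus": "plus"}))
        from evi1kit import TimeCourseMatrix

        swapped = TimeCourseMatrix(
            values=matrix.values, metadata=swapped_meta, probe_to_gene=matrix.probe_to_gene
        )
        assert np.allclose(compute_fold_changes(swapped).to_numpy(), -fcs.to_numpy())


class TestRegulationCall:
    def _fcs(self, matrix, probes=None):
        return compute_fold_changes(matrix, probes)

    def test_no_calls_when_all_fold_changes_zero(self):
        matrix = build_matrix({"a": {}})
        calls = call_regulated(self._fcs(matrix), matrix.probe_to_gene)
        assert calls == []

    def test_exceedance_rule_hand_example_passes(self):
        # clone FCs +1.2 @ 24 h, +2.0 @ 48 h; controls +0.3/+0.1
        # threshold 10^(2/3) * 0.3 = 1.392 <= 2.0 -> called up
        matrix = build_matrix({"a": clone_effect(1.2, 2.0, ctrl=(0.3, 0.1))})
        calls = call_regulated(self._fcs(matrix), matrix.probe_to_gene)
        assert len(calls) == 1 and calls[0].direction == "up"

    def test_exceedance_rule_hand_example_fails_on_larger_background(self):
        # control 0.5: threshold 10^(2/3) * 0.5 = 2.321 > 2.0 -> not called
        matrix = build_matrix({"a": clone_effect(1.2, 2.0, ctrl=(0.5, 0.1))})
        assert call_regulated(self._fcs(matrix), matrix.probe_to_gene) == []

    def test_sub_twofold_at_24h_blocks_call(self):
        matrix = build_matrix({"a": clone_effect(0.9, 3.0)})
        assert call_regulated(self._fcs(matrix), matrix.probe_to_gene) == []

    def test_inconsistent_sign_blocks_call(self):
        conds = clone_effect(1.5, 2.0)
        conds[("E14", "minus", 24)] = 10.0 - 1.5  # down at 24 h in one clone
        matrix = build_matrix({"a": conds})
        assert call_regulated(self._fcs(matrix), matrix.probe_to_gene) == []

    def test_downregulation_called_with_direction_down(self):
        matrix = build_matrix({"a": clone_effect(-1.5, -2.5)})
        calls = call_regulated(self._fcs(matrix), matrix.probe_to_gene)
        assert calls[0].direction == "down"


class TestCollapseAndOrdering:
    def test_single_probe_identity(self):
        matrix = build_matrix({"a": clone_effect(1.5, 2.0)})
        calls = call_regulated(
            compute_fold_changes(matrix), matrix.probe_to_gene
        )
        assert collapse_probesets(calls) == calls

    def test_strongest_probe_kept_per_gene(self):
        matrix = build_matrix(
            {"p1": clone_effect(1.5, 2.0), "p2": clone_effect(2.0, 3.5)},
            probe_to_gene={"p1": "G", "p2": "G"},
        )
        calls = call_regulated(
            compute_fold_changes(matrix), matrix.probe_to_gene
        )
        (kept,) = collapse_probesets(calls)
        assert kept.probe_id == "p2"

    def test_tie_breaks_lexicographically(self):
        matrix = build_matrix(
            {"pB": clone_effect(1.5, 2.0), "pA": clone_effect(1.5, 2.0)},
            probe_to_gene={"pA": "G", "pB": "G"},
        )
        calls = call_regulated(
            compute_fold_changes(matrix), matrix.probe_to_gene
        )
        (kept,) = collapse_probesets(calls)
        assert kept.probe_id == "pA"

    def test_heatmap_order_descends_and_ignores_input_order(self):
        conds = {
            "g1": clone_effect(1.8, 2.0),
            "g2": clone_effect(-3.0, -4.0),
            "g3": clone_effect(1.1, 1.2),
        }
        matrix = build_matrix(conds)
        calls = call_regulated(
            compute_fold_changes(matrix), matrix.probe_to_gene, min_fold=2
        )
        genes, table = order_for_heatmap(collapse_probesets(calls))
        assert genes == ["gene_of_g1", "gene_of_g3", "gene_of_g2"]
        assert order_for_heatmap(collapse_probesets(calls[::-1]))[0] == genes
        assert list(table.gene) == genes


class TestFullChain:
    @pytest.mark.parametrize("seed", [7, 19])
    def test_equals_brute_force_reference(self, seed):
        design = TimeCourseDesign(
            n_probes=120,
            n_regulated_up=10,
            n_regulated_down=10,
            background_log2fc_sd=0.3,
            noise_sd=0.2,
            baseline_log2_range=(2.0, 12.0),  # some probes fail intensity
            shared_gene_fraction=0.2,
            seed=seed,
        )
        matrix, _truth = simulate_timecourse(design)
        genes, table = run_filter(matrix)
        expected = brute_force_regulated(matrix)
        assert set(genes) == set(expected)
        for row in table.itertuples():
            probe, mean48 = expected[row.gene]
            assert row.probe_id == probe

    def test_invariant_to_row_and_column_permutation(self):
        from evi1kit import TimeCourseMatrix

        matrix, _ = simulate_timecourse(
            TimeCourseDesign(n_probes=60, n_regulated_up=6, n_regulated_down=6, seed=3)
        )
        rng = np.random.default_rng(0)
        rows = rng.permutation(matrix.values.index)
        cols = rng.permutation(matrix.values.columns)
        shuffled = TimeCourseMatrix(
            values=matrix.values.loc[rows, cols],
            metadata=matrix.metadata.sample(frac=1, random_state=1),
            probe_to_gene=matrix.probe_to_gene.loc[rows],
        )
        assert run_filter(shuffled)[0] == run_filter(matrix)[0]

    def test_perfect_sensitivity_and_specificity_on_clean_effects(self):
        # effects near the two-fold criterion keep the exceedance bound
        # far above the background tail (see the exceedance-rule tests)
        design = TimeCourseDesign(
            n_probes=300,
            n_regulated_up=15,
            n_regulated_down=15,
            induced_log2fc_range=(1.5, 2.0),
            background_log2fc_sd=0.1,
            noise_sd=0.05,
            seed=23,
        )
        matrix, truth = simulate_timecourse(design)
        genes, _ = run_filter(matrix)
        planted = set(truth.loc[truth.status != "none", "gene"])
        assert set(genes) == planted

    def test_example_design_recovers_at_least_ninety_percent(self):
        design = TimeCourseDesign(
            n_probes=500,
            n_regulated_up=20,
            n_regulated_down=20,
            induced_log2fc_range=(1.0, 4.0),
            background_log2fc_sd=0.1,
            seed=7,
        )
        matrix, truth = simulate_timecourse(design)
        genes, _ = run_filter(matrix)
        planted = set(truth.loc[truth.status != "none", "gene"])
        assert len(set(genes) & planted) / len(planted) >= 0.9
        assert not set(genes) - planted
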