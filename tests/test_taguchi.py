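"""Orthogonal array construction, S/N analysis, selection and proposals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanodoe import (
    DesignTable,
    FactorSpec,
    attach_levels,
    build_orthogonal_array,
    count_variant_space,
    main_effects,
    propose_variants,
    sn_larger_is_better,
    summarize_design,
    verify_orthogonality,
)
from nanodoe.taguchi import PAPER_LEVELS, OrthogonalArray


class TestArrayConstruction:
    def test_l25_first_row_is_all_level_one(self):
        arr = build_orthogonal_array(5, 6)
        assert arr.n_runs == 25
        assert arr.row(1) == (1, 1, 1, 1, 1, 1)

    def test_l25_row_nine(self):
        assert build_orthogonal_array(5, 6).row(9) == (2, 4, 5, 1, 2, 3)

    def test_two_level_case_is_the_full_factorial(self):
        arr = build_orthogonal_array(2, 2)
        assert {arr.row(r) for r in range(1, 5)} == {(1, 1), (1, 2), (2, 1), (2, 2)}

    @pytest.mark.parametrize("bad", [4, 6, 1, 9])
    def test_non_prime_levels_rejected(self, bad):
        with pytest.raises(ValueError, match="prime"):
            build_orthogonal_array(bad, 2)

    @pytest.mark.parametrize("n_factors", [1, 7])
    def test_factor_count_out_of_range_rejected(self, n_factors):
        with pytest.raises(ValueError):
            build_orthogonal_array(5, n_factors)

    @settings(deadline=None, max_examples=20)
    @given(st.sampled_from([2, 3, 5, 7]), st.data())
    def test_construction_always_orthogonal(self, n_levels, data):
        n_factors = data.draw(st.integers(2, n_levels + 1))
        report = verify_orthogonality(build_orthogonal_array(n_levels, n_factors))
        assert report.passed
        assert all(
            c == report.expected_count
            for counts in report.pair_counts.values()
            for c in counts.values()
        )

    def test_duplicated_column_fails_orthogonality(self):
        arr = build_orthogonal_array(5, 6)
        entries = arr.entries.copy()
        entries[:, 1] = entries[:, 0]
        bad = OrthogonalArray(25, 6, 5, entries)
        assert not verify_orthogonality(bad).passed

    def test_single_column_vacuously_passes(self):
        arr = build_orthogonal_array(3, 2)
        one_col = OrthogonalArray(9, 1, 3, arr.entries[:, :1])
        assert verify_orthogonality(one_col).passed


class TestDesignTable:
    def test_reference_run_six(self, reference_design):
        row = reference_design.rows[5]
        assert [row[p] for p in (27, 28, 29, 31, 99, 100)] == [
            "Phe", "Trp", "Phe", "His", "Asp", "Tyr"
        ]
        assert reference_design.responses[5] == -705

    def test_design_without_responses_is_refused_by_analysis(self, factors):
        design = attach_levels(build_orthogonal_array(5, 6), factors)
        with pytest.raises(ValueError, match="responses"):
            main_effects(design)
        with pytest.raises(ValueError, match="responses"):
            summarize_design(design)

    def test_mixed_sign_or_zero_responses_rejected(self, factors):
        arr = build_orthogonal_array(5, 6)
        good = [-700.0] * 25
        for bad in ([0.0] + [-1.0] * 24, [-700.0] * 24 + [5.0]):
            with pytest.raises(ValueError, match="uniformly signed"):
                attach_levels(arr, factors, bad)
        assert attach_levels(arr, factors, good).responses is not None

    def test_level_count_mismatch_rejected(self):
        arr = build_orthogonal_array(5, 6)
        three = [FactorSpec(p, ("Trp", "Phe", "His")) for p in (27, 28, 29, 31, 99, 100)]
        with pytest.raises(ValueError, match="levels"):
            attach_levels(arr, three)

    def test_csv_round_trip(self, reference_design, tmp_path):
        path = tmp_path / "design.csv"
        reference_design.to_frame().to_csv(path, index=False)
        back = DesignTable.from_frame(pd.read_csv(path))
        assert back.rows == reference_design.rows
        np.testing.assert_allclose(back.responses, reference_design.responses)


class TestSignalToNoise:
    def test_unit_magnitude_gives_zero_db(self):
        assert sn_larger_is_better([1.0])[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_replicate_reduces_to_20log10(self):
        # |E| of the design's first run
        assert sn_larger_is_better([750.0])[0] == pytest.approx(20 * np.log10(750), abs=1e-9)
        assert sn_larger_is_better([750.0])[0] == pytest.approx(57.5012253, abs=1e-6)

    def test_constant_replicates(self):
        assert sn_larger_is_better([[10.0, 10.0]])[0] == pytest.approx(20.0)

    def test_nonpositive_magnitudes_rejected(self):
        with pytest.raises(ValueError):
            sn_larger_is_better([750.0, 0.0])


class TestMainEffects:
    def test_published_best_levels_selected(self, reference_design):
        effects = main_effects(reference_design)
        assert effects.selected[27] == ["Phe"]
        assert effects.selected[28] == ["Trp", "Tyr"]  # the documented two-way tie
        assert effects.selected[29] == ["Tyr"]
        assert effects.selected[31] == ["Trp"]
        assert effects.selected[99] == ["Phe"]
        assert effects.selected[100] == ["His"]

    def test_tyr_at_29_arithmetic_mean_energy(self, reference_design):
        # mean |E| over the five runs where position 29 carries Tyr
        col = [row[29] for row in reference_design.rows]
        mask = np.array(col) == "Tyr"
        assert np.abs(reference_design.responses)[mask].mean() == pytest.approx(721.0)

    def test_grand_mean_conservation(self, reference_design):
        effects = main_effects(reference_design)
        sn = sn_larger_is_better(np.abs(reference_design.responses))
        for pos in (27, 28, 29, 31, 99, 100):
            level_means = effects.means.loc[pos, list(PAPER_LEVELS)]
            assert level_means.mean() == pytest.approx(sn.mean(), abs=1e-9)

    def test_run_permutation_invariance(self, reference_design):
        rng = np.random.default_rng(0)
        perm = rng.permutation(25)
        shuffled = DesignTable(
            factors=reference_design.factors,
            rows=[reference_design.rows[i] for i in perm],
            responses=reference_design.responses[perm],
        )
        a, b = main_effects(reference_design), main_effects(shuffled)
        pd.testing.assert_frame_equal(a.means, b.means)
        assert a.selected == b.selected

    def test_level_relabeling_maps_selection(self, reference_design):
        reordered_factors = [FactorSpec(f.position, tuple(reversed(f.levels)))
                             for f in reference_design.factors]
        relabeled = DesignTable(
            factors=reordered_factors,
            rows=reference_design.rows,
            responses=reference_design.responses,
        )
        a, b = main_effects(reference_design), main_effects(relabeled)
        assert {p: set(v) for p, v in a.selected.items()} == {p: set(v) for p, v in b.selected.items()}

    def test_positive_scaling_shifts_all_means_equally(self, reference_design):
        scaled = DesignTable(
            factors=reference_design.factors,
            rows=reference_design.rows,
            responses=reference_design.responses * 10.0,
        )
        a, b = main_effects(reference_design), main_effects(scaled)
        shift = b.means - a.means
        vals = shift.to_numpy()
        assert np.allclose(vals[~np.isnan(vals)], 20.0)  # 20*log10(10) dB
        assert a.selected == b.selected

    def test_unbalanced_design_rejected(self, reference_design):
        rows = [dict(r) for r in reference_design.rows]
        rows[0][27] = "Tyr"  # Trp now appears 4x, Tyr 6x in the first column
        broken = DesignTable(reference_design.factors, rows, reference_design.responses)
        with pytest.raises(ValueError, match="unbalanced"):
            main_effects(broken)


class TestProposalsAndSummary:
    def test_reference_effects_yield_the_two_published_variants(self, reference_design):
        effects = main_effects(reference_design)
        variants = propose_variants(effects)
        assert len(variants) == 2
        nb2 = {27: "Phe", 28: "Trp", 29: "Tyr", 31: "Trp", 99: "Phe", 100: "His"}
        nb1 = {27: "Phe", 28: "Tyr", 29: "Tyr", 31: "Trp", 99: "Phe", 100: "His"}
        assert variants == [nb2, nb1]  # level order puts Trp before Tyr

    def test_singleton_and_product_orders(self, reference_design):
        effects = main_effects(reference_design)
        effects.selected = {p: [v[0]] for p, v in effects.selected.items()}
        assert len(propose_variants(effects)) == 1
        effects.selected[27] = ["Trp", "Phe"]
        effects.selected[28] = ["His", "Asp"]
        combos = [(v[27], v[28]) for v in propose_variants(effects)]
        assert combos == [("Trp", "His"), ("Trp", "Asp"), ("Phe", "His"), ("Phe", "Asp")]

    def test_proposal_cap(self, reference_design):
        effects = main_effects(reference_design)
        effects.selected = {p: list(PAPER_LEVELS) for p in effects.selected}
        with pytest.raises(ValueError, match="tie_tol"):
            propose_variants(effects, cap=64)

    def test_variant_space_counts(self, factors):
        assert count_variant_space(factors) == 15_625
        mixed = [FactorSpec(1, ("A", "C")), FactorSpec(2, ("A", "C", "D")),
                 FactorSpec(3, ("A", "C", "D", "E"))]
        assert count_variant_space(mixed) == 24

    def test_best_run_and_reference_count(self, reference_design):
        s = summarize_design(reference_design, reference_energy=-745.6)
        assert (s.best_run, s.best_energy) == (9, -791.0)
        # independent scan of the packaged energies
        assert s.n_below_reference == int((reference_design.responses < -745.6).sum())
        assert s.n_below_reference == 2

    def test_single_run_design(self):
        design = DesignTable(
            factors=[FactorSpec(1, ("Trp", "Phe"))], rows=[{1: "Trp"}],
            responses=np.array([-500.0]),
        )
        s = summarize_design(design)
        assert s.best_run == s.worst_run == 1
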