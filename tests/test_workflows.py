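import numpy as np
import pandas as pd
import pytest

from idakit import test_vs_control as run_test_vs_control
from idakit import (
    ConcentrationCapTable,
    ConfigurationError,
    Treatment,
    apply_caps,
    combo_metrics,
    control_plus_one_batch,
    control_plus_one_focused,
    make_disjoint_pair_fixture,
    simulate_screen,
    default_config,
    two_drug_batch,
    two_drug_focused,
    write_metadata,
    write_table,
)

from conftest import make_screen, random_screen


@pytest.fixture
def grid_screen():
    """2 models x 2 drugs x 2 doses, fully crossed, hand-checkable."""
    rows = []
    for model, effs in (("L1", [0.9, 0.3, 0.8, 0.6]), ("L2", [0.7, 0.5, 0.95, 0.2])):
        rows += [
            (model, "A", 1.0, effs[0]),
            (model, "A", 10.0, effs[1]),
            (model, "B", 2.0, effs[2]),
            (model, "B", 20.0, effs[3]),
        ]
    return make_screen(rows)


class TestTwoDrugFocused:
    def test_grid_cells_hand_computed(self, grid_screen):
        g = two_drug_focused(grid_screen, "A", [1.0, 10.0], "B", [2.0, 20.0]).grid
        assert len(g) == 4
        cell = g[(g.conc_a == 1.0) & (g.conc_b == 20.0)].iloc[0]
        # minima: L1 min(0.9, 0.6) = 0.6; L2 min(0.7, 0.2) = 0.2
        assert cell.mean_efficacy_combo == pytest.approx(0.4)
        assert cell.mean_efficacy_a == pytest.approx(0.8)
        assert cell.mean_efficacy_b == pytest.approx(0.4)
        # better mono is B (0.4); combo matches it exactly
        assert cell.hr_vs_best_mono == pytest.approx(1.0)
        assert cell.idacomboscore == pytest.approx(0.0)
        cell = g[(g.conc_a == 10.0) & (g.conc_b == 20.0)].iloc[0]
        # minima: L1 min(0.3, 0.6) = 0.3; L2 min(0.5, 0.2) = 0.2 -> 0.25
        assert cell.mean_efficacy_combo == pytest.approx(0.25)
        assert cell.hr_vs_best_mono == pytest.approx(0.25 / 0.4)
        assert cell.idacomboscore == pytest.approx((0.4 - 0.25) * (1 - 0.25 / 0.4))

    def test_rows_sorted_and_complete(self, rng):
        screen = random_screen(rng, n_models=6, n_drugs=2, max_concs=3)
        ca = list(screen.concentrations("D0"))
        cb = list(screen.concentrations("D1"))
        g = two_drug_focused(screen, "D0", ca, "D1", cb).grid
        assert len(g) == len(ca) * len(cb)
        assert list(g[["conc_a", "conc_b"]].itertuples(index=False)) == sorted(
            g[["conc_a", "conc_b"]].itertuples(index=False)
        )

    def test_neutral_partner_leaves_monotherapy_unchanged(self, grid_screen):
        neutral = pd.DataFrame(
            [("L1", "N", 1.0, 1.0), ("L2", "N", 1.0, 1.0)],
            columns=["model_id", "drug", "concentration", "efficacy"],
        )
        screen = type(grid_screen)(
            data=pd.concat([grid_screen.data, neutral], ignore_index=True),
            lower_is_better=True,
        )
        g = two_drug_focused(screen, "A", [1.0, 10.0], "N", [1.0]).grid
        assert np.allclose(g.mean_efficacy_combo, g.mean_efficacy_a)

    def test_self_pair_diagonal_hr_is_one(self, grid_screen):
        g = two_drug_focused(grid_screen, "A", [1.0, 10.0], "A", [1.0, 10.0]).grid
        diag = g[g.conc_a == g.conc_b]
        assert np.allclose(diag.hr_vs_best_mono, 1.0)
        assert np.allclose(diag.idacomboscore, 0.0)

    def test_unknown_concentration_names_drug_and_value(self, grid_screen):
        from idakit import ScreenLookupError

        with pytest.raises(ScreenLookupError, match=r"5.*'A'|'A'.*5"):
            two_drug_focused(grid_screen, "A", [5.0], "B", [2.0])


class TestTwoDrugBatch:
    def test_row_counts(self, grid_screen):
        extra = pd.DataFrame(
            [(m, "C", c, v) for m, c, v in
             [("L1", 1.0, 0.5), ("L2", 1.0, 0.6), ("L1", 3.0, 0.4), ("L2", 3.0, 0.3)]],
            columns=["model_id", "drug", "concentration", "efficacy"],
        )
        screen = type(grid_screen)(
            data=pd.concat([grid_screen.data, extra], ignore_index=True), lower_is_better=True
        )
        pt = two_drug_batch(screen, "A", ["B", "C"])
        assert len(pt.table) == 2 * 2 + 2 * 2  # two candidates x (2x2) grids
        assert len(pt.ranking) == 2

    def test_anchor_candidate_skipped_with_warning(self, grid_screen):
        with pytest.warns(UserWarning, match="anchor"):
            pt = two_drug_batch(grid_screen, "A", ["A", "B"])
        assert set(pt.ranking["drug_b"]) == {"B"}

    def test_ranking_rows_match_focused_recomputation(self, rng):
        screen = random_screen(rng, n_models=12, n_drugs=4, max_concs=3)
        pt = two_drug_batch(screen, "D0", ["D1", "D2", "D3"])
        for _, row in pt.ranking.iterrows():
            focused = two_drug_focused(
                screen,
                "D0",
                list(screen.concentrations("D0")),
                row["drug_b"],
                list(screen.concentrations(row["drug_b"])),
            ).grid
            cell = focused[
                (focused.conc_a == row["conc_a"]) & (focused.conc_b == row["conc_b"])
            ].iloc[0]
            assert row["mean_efficacy_combo"] == cell["mean_efficacy_combo"]  # bit-identical
            assert row["hr_vs_control"] == cell["hr_vs_best_mono"]
            assert row["idacomboscore"] == cell["idacomboscore"]

    def test_top_ranked_equals_exhaustive_argmax(self, rng):
        screen = random_screen(rng, n_models=10, n_drugs=4, max_concs=2)
        pt = two_drug_batch(screen, "D0", ["D1", "D2", "D3"], rank_by="idacomboscore")
        best = pt.ranking["idacomboscore"].max()
        assert pt.ranking["idacomboscore"].iloc[0] == best
        by_hr = two_drug_batch(screen, "D0", ["D1", "D2", "D3"], rank_by="hr")
        assert by_hr.ranking["hr_vs_control"].iloc[0] == by_hr.ranking["hr_vs_control"].min()

    def test_complementary_candidate_ranks_first(self):
        screen = make_disjoint_pair_fixture(8)
        pt = two_drug_batch(screen, "A", ["B", "A_copy"], rank_by="idacomboscore")
        assert pt.ranking.iloc[0]["drug_b"] == "B"
        assert pt.ranking.iloc[-1]["idacomboscore"] == pytest.approx(0.0)

    def test_cap_then_rank_equals_rank_on_capped_screen(self, rng):
        screen = random_screen(rng, n_models=8, n_drugs=3, max_concs=3)
        caps = ConcentrationCapTable(
            {"D1": float(np.median(screen.concentrations("D1")))}
        )
        capped = apply_caps(screen, caps)
        pt = two_drug_batch(capped, "D0", ["D1", "D2"])
        assert (pt.ranking["conc_b"] <= np.inf).all()
        for _, row in pt.ranking.iterrows():
            assert row["conc_a"] == capped.max_concentration("D0")
            assert row["conc_b"] == capped.max_concentration(row["drug_b"])


class TestControlPlusOne:
    def test_neutral_added_drug_scores_zero(self, grid_screen):
        neutral = pd.DataFrame(
            [("L1", "N", 1.0, 1.0), ("L2", "N", 1.0, 1.0)],
            columns=["model_id", "drug", "concentration", "efficacy"],
        )
        screen = type(grid_screen)(
            data=pd.concat([grid_screen.data, neutral], ignore_index=True), lower_is_better=True
        )
        pt = control_plus_one_focused(screen, Treatment((("A", 10.0),)), "N", [1.0])
        row = pt.table.iloc[0]
        assert row.hr_vs_control == pytest.approx(1.0)
        assert row.idacomboscore == pytest.approx(0.0)

    def test_single_drug_control_matches_two_drug_grid(self, grid_screen):
        pt = control_plus_one_focused(grid_screen, Treatment((("A", 10.0),)), "B", [2.0, 20.0])
        grid = two_drug_focused(grid_screen, "A", [10.0], "B", [2.0, 20.0]).grid
        for conc in (2.0, 20.0):
            cp1 = pt.table[pt.table.added_conc == conc].iloc[0]
            cell = grid[grid.conc_b == conc].iloc[0]
            assert cp1.mean_efficacy_combo == cell.mean_efficacy_combo

    def test_hr_vs_added_drug_exposes_dominant_addition(self):
        # B dominates A in every model: combo == B alone, so HR vs added drug = 1
        screen = make_screen(
            [("L1", "A", 1.0, 0.8), ("L2", "A", 1.0, 0.9),
             ("L1", "B", 1.0, 0.4), ("L2", "B", 1.0, 0.5)]
        )
        pt = control_plus_one_focused(screen, Treatment((("A", 1.0),)), "B", [1.0])
        row = pt.table.iloc[0]
        assert row.hr_vs_control == pytest.approx(0.45 / 0.85)
        assert row.hr_vs_added_drug == pytest.approx(1.0)

    def test_added_drug_already_in_control_rejected(self, grid_screen):
        with pytest.raises(ConfigurationError, match="already"):
            control_plus_one_focused(grid_screen, Treatment((("A", 1.0),)), "A", [10.0])

    def test_batch_counts_and_path_equivalence(self, grid_screen):
        pt = control_plus_one_batch(grid_screen, Treatment((("A", 1.0),)), ["B"])
        assert len(pt.table) == 2  # B has two doses
        assert len(pt.ranking) == 1
        focused = control_plus_one_focused(
            grid_screen, Treatment((("A", 1.0),)), "B", [20.0]
        ).table.iloc[0]
        ranked = pt.ranking.iloc[0]
        assert ranked["mean_efficacy_combo"] == focused["mean_efficacy_combo"]
        assert ranked["hr_vs_control"] == focused["hr_vs_control"]
        assert ranked["added_conc"] == 20.0

    def test_candidate_in_control_skipped_with_warning(self, grid_screen):
        with pytest.warns(UserWarning, match="already in the control"):
            pt = control_plus_one_batch(grid_screen, Treatment((("A", 1.0),)), ["A", "B"])
        assert set(pt.table["added_drug"]) == {"B"}

    def test_neutral_candidates_tie_break_alphabetical(self, grid_screen):
        neutral = pd.DataFrame(
            [(m, d, 1.0, 1.0) for m in ("L1", "L2") for d in ("N2", "N1")],
            columns=["model_id", "drug", "concentration", "efficacy"],
        )
        screen = type(grid_screen)(
            data=pd.concat([grid_screen.data, neutral], ignore_index=True), lower_is_better=True
        )
        pt = control_plus_one_batch(screen, Treatment((("A", 10.0),)), ["N2", "N1"])
        assert (pt.ranking["idacomboscore"] == 0).all()
        labels = list(pt.ranking["label"])
        assert labels == sorted(labels)


class TestTestVsControl:
    def test_identical_therapies_neutral_no_warning(self, grid_screen, recwarn):
        t = Treatment((("A", 1.0), ("B", 2.0)))
        result = run_test_vs_control(grid_screen, t, t)
        assert result.metrics.hazard_ratio == pytest.approx(1.0)
        assert not result.non_superset_warning
        assert not [w for w in recwarn if "not validated" in str(w.message)]

    def test_superset_test_improves_or_matches(self, grid_screen, recwarn):
        control = Treatment((("A", 10.0),))
        test = Treatment((("A", 10.0), ("B", 20.0)))
        result = run_test_vs_control(grid_screen, test, control)
        assert result.metrics.hazard_ratio <= 1.0
        assert not result.non_superset_warning

    def test_non_superset_flags_warning_but_computes(self, grid_screen):
        with pytest.warns(UserWarning, match="not validated"):
            result = run_test_vs_control(
                grid_screen, Treatment((("B", 20.0),)), Treatment((("A", 10.0),))
            )
        assert result.non_superset_warning
        assert result.metrics.hazard_ratio is not None
        frame = result.to_frame()
        assert bool(frame["non_superset_warning"].iloc[0])

    def test_matches_combo_metrics(self, grid_screen):
        test = Treatment((("A", 10.0), ("B", 20.0)))
        control = Treatment((("A", 10.0),))
        result = run_test_vs_control(grid_screen, test, control)
        direct = combo_metrics(grid_screen, test, control)
        assert result.metrics == direct


class TestOutput:
    def test_write_table_tab_delimited(self, tmp_path, grid_screen):
        g = two_drug_focused(grid_screen, "A", [1.0], "B", [2.0])
        path = write_table(g.grid, tmp_path / "grid.tsv")
        lines = path.read_text().splitlines()
        assert lines[0].split("\t")[:2] == ["conc_a", "conc_b"]
        assert len(lines) == 2

    def test_write_metadata_key_value(self, tmp_path):
        path = write_metadata({"b": 1, "a": "x"}, tmp_path / "meta.txt")
        assert path.read_text() == "a=x\nb=1\n"
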