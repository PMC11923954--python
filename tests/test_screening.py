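"""Plate normalization, the log2 response transform, and screen categories."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgccscreen import screening
from pgccscreen.imaging import WellCounts


def _well(well_id, pgcc, nonpgcc, dead=0):
    return WellCounts(
        well_id=well_id,
        n_live=pgcc + nonpgcc,
        n_dead=dead,
        n_pgcc=pgcc,
        n_nonpgcc=nonpgcc,
    )


@pytest.fixture()
def layout():
    return screening.PlateLayout(
        plate_id="P1",
        control_wells=["A01", "A02"],
        compound_wells={"B01": "drugA", "B02": "drugB"},
    )


class TestNormalizePlate:
    def test_hand_computed_ratios(self, layout):
        counts = [
            _well("A01", pgcc=10, nonpgcc=90),   # controls: mean pgcc 10,
            _well("A02", pgcc=10, nonpgcc=110),  # nonpgcc 100, total 110
            _well("B01", pgcc=25, nonpgcc=19),
            _well("B02", pgcc=10, nonpgcc=100),
        ]
        table = screening.normalize_plate(counts, layout).set_index("compound_id")
        assert table.loc["drugA", "norm_pgcc"] == pytest.approx(2.5)
        assert table.loc["drugA", "norm_total"] == pytest.approx(44 / 110)
        # compound matching control means -> all ratios 1
        for col in ("norm_pgcc", "norm_nonpgcc", "norm_total"):
            assert table.loc["drugB", col] == pytest.approx(1.0)

    def test_zero_control_flags_not_raises(self):
        layout = screening.PlateLayout(
            plate_id="P1", control_wells=["A01"], compound_wells={"B01": "d"}
        )
        counts = [_well("A01", pgcc=0, nonpgcc=50), _well("B01", pgcc=3, nonpgcc=10)]
        table = screening.normalize_plate(counts, layout)
        row = table.iloc[0]
        assert row["excluded"]
        assert "zero control" in row["excluded_reason"]
        assert np.isnan(row["norm_pgcc"]) and np.isnan(row["y_target"])
        assert row["norm_total"] == pytest.approx(13 / 50)

    def test_no_control_wells_is_an_error(self):
        with pytest.raises(ValueError):
            screening.PlateLayout(plate_id="P1", control_wells=[], compound_wells={})

    def test_scale_invariance(self, layout):
        """Multiplying every count on the plate by k leaves ratios unchanged."""
        base = [
            _well("A01", 8, 80),
            _well("A02", 12, 120),
            _well("B01", 5, 30),
            _well("B02", 40, 10),
        ]
        scaled = [
            _well(w.well_id, 3 * w.n_pgcc, 3 * w.n_nonpgcc, 3 * w.n_dead) for w in base
        ]
        t1 = screening.normalize_plate(base, layout)
        t2 = screening.normalize_plate(scaled, layout)
        for col in ("norm_pgcc", "norm_nonpgcc", "norm_total", "y_target"):
            np.testing.assert_allclose(t1[col], t2[col])

    def test_median_statistic_option(self, layout):
        counts = [
            _well("A01", 10, 10),
            _well("A02", 30, 10),
            _well("B01", 20, 10),
            _well("B02", 20, 10),
        ]
        mean_t = screening.normalize_plate(counts, layout).set_index("compound_id")
        med_t = screening.normalize_plate(counts, layout, statistic="median")
        assert mean_t.loc["drugA", "norm_pgcc"] == pytest.approx(1.0)
        assert med_t.set_index("compound_id").loc["drugA", "norm_pgcc"] == pytest.approx(1.0)


class TestTransformResponse:
    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (0.0, np.log2(1e-3)),        # ~ -9.9658
            (1.0, np.log2(1.001)),       # ~ 0.001442
            (0.5, np.log2(0.501)),       # ~ -0.99712
        ],
    )
    def test_closed_form(self, ratio, expected):
        assert screening.transform_response(ratio) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            screening.transform_response(-0.1)

    @given(st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    @settings(deadline=None, max_examples=100)
    def test_monotone_and_invertible(self, ratio):
        y = screening.transform_response(ratio)
        back = screening.inverse_transform_response(y)
        assert back == pytest.approx(ratio, abs=1e-9, rel=1e-9)
        assert screening.transform_response(ratio + 0.5) > y


class TestCategories:
    @pytest.mark.parametrize(
        "total, pgcc, nonpgcc, expected",
        [
            (0.4, 2.5, 0.3, {"total_inhibited", "pgcc_enriched"}),
            (
                0.45,
                0.05,
                0.45,
                {"total_inhibited", "pgcc_reduced_2x", "pgcc_reduced_10x", "dual_inhibitor"},
            ),
            (1.0, 1.0, 1.0, set()),
            # inclusive boundaries
            (0.5, 2.0, 0.5, {"total_inhibited", "pgcc_enriched"}),
            (1.0, 0.5, 0.5, {"pgcc_reduced_2x", "dual_inhibitor"}),
            (1.0, 0.1, 1.0, {"pgcc_reduced_2x", "pgcc_reduced_10x"}),
        ],
    )
    def test_rule_application(self, total, pgcc, nonpgcc, expected):
        assert screening.categorize_compound(total, pgcc, nonpgcc) == expected

    def test_undefined_ratio_unclassifiable(self):
        with pytest.raises(ValueError):
            screening.categorize_compound(np.nan, 1.0, 1.0)

    @given(
        st.floats(0, 20, allow_nan=False),
        st.floats(0, 20, allow_nan=False),
        st.floats(0, 20, allow_nan=False),
    )
    @settings(deadline=None, max_examples=200)
    def test_ten_fold_implies_two_fold(self, total, pgcc, nonpgcc):
        flags = screening.categorize_compound(total, pgcc, nonpgcc)
        if "pgcc_reduced_10x" in flags:
            assert "pgcc_reduced_2x" in flags


class TestSummarizeScreen:
    @staticmethod
    def _random_table(rng, n):
        return pd.DataFrame(
            {
                "compound_id": [f"c{i}" for i in range(n)],
                "norm_pgcc": rng.uniform(0, 4, n),
                "norm_nonpgcc": rng.uniform(0, 4, n),
                "norm_total": rng.uniform(0, 4, n),
            }
        )

    def test_excluded_compounds_removed_before_thresholding(self, rng):
        table = self._random_table(rng, 50)
        excl = [f"c{i}" for i in range(10)]
        summary = screening.summarize_screen(table, exclusions=excl)
        assert summary["library_size"] == 50
        assert summary["excluded"] == 10
        assert summary["screened"] == 40

    def test_empty_exclusions(self, rng):
        table = self._random_table(rng, 25)
        summary = screening.summarize_screen(table)
        assert summary["screened"] == summary["library_size"] == 25

    def test_unknown_exclusion_warns(self, rng):
        table = self._random_table(rng, 5)
        with pytest.warns(UserWarning):
            summary = screening.summarize_screen(table, exclusions=["nope"])
        assert summary["screened"] == 5

    def test_matches_brute_force_recount(self, rng):
        """Category tallies equal an independent row-by-row filter."""
        table = self._random_table(rng, 400)
        excl = list(rng.choice(table["compound_id"], size=30, replace=False))
        summary = screening.summarize_screen(table, exclusions=excl)
        kept = table[~table["compound_id"].isin(excl)]
        assert summary["total_inhibited"] == int((kept.norm_total <= 0.5).sum())
        assert summary["pgcc_enriched"] == int((kept.norm_pgcc >= 2).sum())
        assert summary["pgcc_reduced_2x"] == int((kept.norm_pgcc <= 0.5).sum())
        assert summary["pgcc_reduced_10x"] == int((kept.norm_pgcc <= 0.1).sum())
        assert summary["dual_inhibitor"] == int(
            ((kept.norm_pgcc <= 0.5) & (kept.norm_nonpgcc <= 0.5)).sum()
        )

    def test_undefined_rows_counted_unclassifiable(self, rng):
        table = self._random_table(rng, 10)
        table.loc[3, "norm_pgcc"] = np.nan
        summary = screening.summarize_screen(table)
        assert summary["unclassifiable"] == 1
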