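"""Ki curation rules and the spKi transform."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from structpcm import (
    RawActivityRecord,
    Relation,
    apply_relation_rules,
    curate_activities,
    filter_targets,
    resolve_duplicates,
    spki,
    spki_to_ki,
    standardize_units,
)


def rec(relation="=", value=10.0, units="nM", comment=None, year=2010,
        mol="M1", tgt="T1", activity_type="Ki"):
    return RawActivityRecord(
        molecule_id=mol, target_id=tgt, activity_type=activity_type,
        relation=Relation.parse(relation), value=value, units=units,
        comment=comment, year=year,
    )


class TestSpki:
    @pytest.mark.parametrize("ki,expected", [
        (0.5, 1.0),          # sub-nanomolar: very active
        (1.0, 1.0),          # boundary, continuous with (4-0)/4
        (100.0, 0.5),        # midpoint of the log scale
        (10_000.0, 0.0),     # boundary, continuous with (4-4)/4
        (20_000.0, 0.0),     # inactive concentration
    ])
    def test_transform_values(self, ki, expected):
        assert spki(ki) == pytest.approx(expected, abs=1e-12)

    def test_inactive_flag(self):
        assert spki(inactive=True) == 0.0

    def test_nonpositive_ki_rejected(self):
        with pytest.raises(ValueError):
            spki(0.0)
        with pytest.raises(ValueError):
            spki(-1.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(min_value=0.001, max_value=1e6),
           st.floats(min_value=1.0, max_value=10.0))
    def test_monotone_non_increasing_in_ki(self, ki, factor):
        assert spki(ki * factor) <= spki(ki) + 1e-12

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.001, max_value=0.999))
    def test_inverse_transform_round_trip(self, score):
        assert spki(spki_to_ki(score)) == pytest.approx(score, abs=1e-9)


class TestUnits:
    @pytest.mark.parametrize("value,units,expected_nM", [
        (1.0, "uM", 1000.0),
        (1.0, "µM", 1000.0),
        (1.0, "nM", 1.0),
        (2.5, "pM", 0.0025),
        (1e-9, "M", 1.0),
        (3.0, "mM", 3e6),
    ])
    def test_molar_units_converted(self, value, units, expected_nM):
        out, reason = standardize_units(rec(value=value, units=units))
        assert reason is None
        assert out.value == pytest.approx(expected_nM)
        assert out.units == "nM"

    @pytest.mark.parametrize("units", ["%", "ug.mL-1", "", "parsecs"])
    def test_unrecognized_units_excluded_with_reason(self, units):
        out, reason = standardize_units(rec(units=units))
        assert out is None and units in reason


class TestRelationRules:
    def test_plain_measurement_kept(self):
        out = apply_relation_rules([rec(value=50.0)])
        assert [r.value for r in out.measured] == [50.0]
        assert not out.inactive and out.upper_bound is None

    def test_upper_bound_uses_highest_censored_value(self):
        out = apply_relation_rules([
            rec("<", 100.0), rec("<", 500.0, year=2005),
        ])
        assert out.upper_bound.value == 500.0
        assert not out.measured
        reasons = [r for _rec, r in out.exclusions]
        assert reasons == ["lower upper-bound not selected"]

    def test_gt_relation_means_inactive(self):
        out = apply_relation_rules([rec(">", 10_000.0)])
        assert out.inactive and not out.measured

    def test_measured_wins_over_censored_and_inactive(self):
        out = apply_relation_rules([
            rec("=", 50.0), rec("<", 10.0), rec(">", 1000.0),
        ])
        assert [r.value for r in out.measured] == [50.0]
        assert out.upper_bound is None and not out.inactive
        assert len(out.exclusions) == 2

    def test_eq_without_value_and_bare_rows_excluded(self):
        out = apply_relation_rules([
            rec("=", None),
            rec("none", None, comment=None),
            rec("none", None, comment="active"),
        ])
        assert not out.measured and not out.inactive
        assert len(out.exclusions) == 3

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            apply_relation_rules([rec(mol="M1"), rec(mol="M2")])


class TestResolveDuplicates:
    def test_within_one_order_of_magnitude_geometric_mean(self):
        # 10 and 50 nM agree within 10x: 10^((1 + log10 50)/2) = sqrt(500)
        assert resolve_duplicates([10.0, 50.0], [2001, 2002]) == (
            pytest.approx(math.sqrt(500), rel=1e-12)
        )

    def test_beyond_one_order_of_magnitude_most_recent_wins(self):
        assert resolve_duplicates([10.0, 500.0], [2005, 2010]) == 500.0
        assert resolve_duplicates([500.0, 10.0], [2010, 2005]) == 500.0

    def test_recency_tie_falls_back_to_geometric_mean_of_tied(self):
        out = resolve_duplicates([10.0, 1000.0], [2010, 2010])
        assert out == pytest.approx(100.0)

    def test_single_value_is_itself(self):
        assert resolve_duplicates([42.0], [1999]) == 42.0

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(
        st.tuples(st.floats(min_value=0.1, max_value=1e5),
                  st.integers(min_value=1990, max_value=2024)),
        min_size=2, max_size=6,
    ))
    def test_permutation_invariance(self, pairs):
        values = [v for v, _ in pairs]
        years = [y for _, y in pairs]
        ref = resolve_duplicates(values, years)
        assert resolve_duplicates(values[::-1], years[::-1]) == (
            pytest.approx(ref, rel=1e-12)
        )


def raw_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["molecule_id", "target_id", "activity_type", "relation",
                 "value", "units", "comment", "year"],
    )


class TestPipeline:
    def test_record_conservation(self):
        raw = raw_frame([
            ("M1", "T1", "Ki", "=", 50.0, "nM", None, 2001),
            ("M1", "T1", "Ki", "=", 80.0, "nM", None, 2002),
            ("M2", "T1", "Ki", "<", 100.0, "nM", None, 2001),
            ("M3", "T1", "Ki", ">", 10000.0, "nM", None, 2001),
            ("M4", "T1", "Ki", "=", 5.0, "%", None, 2001),
            ("M5", "T1", "IC50", "=", 5.0, "nM", None, 2001),
            ("M6", "T1", "Ki", "=", None, "nM", None, 2001),
        ])
        result = curate_activities(raw)
        assert result.conservation_holds()
        assert set(result.curated["molecule_id"]) == {"M1", "M2", "M3"}
        # every excluded row appears exactly once
        assert result.exclusions["row"].is_unique

    def test_curated_labels(self):
        raw = raw_frame([
            ("M1", "T1", "Ki", "=", 10.0, "nM", None, 2001),
            ("M1", "T1", "Ki", "=", 50.0, "nM", None, 2002),
            ("M2", "T1", "Ki", "=", 0.1, "uM", None, 2001),
            ("M3", "T1", "Ki", ">", 10000.0, "nM", None, 2001),
        ])
        curated = curate_activities(raw).curated.set_index("molecule_id")
        assert curated.loc["M1", "ki_nM"] == pytest.approx(math.sqrt(500))
        assert curated.loc["M2", "ki_nM"] == pytest.approx(100.0)
        assert curated.loc["M2", "spki"] == pytest.approx(0.5)
        assert curated.loc["M3", "spki"] == 0.0
        assert curated.loc["M3", "provenance"] == "inactive_by_relation"

    def test_curation_idempotent(self):
        raw = raw_frame([
            ("M1", "T1", "Ki", "=", 10.0, "nM", None, 2001),
            ("M1", "T1", "Ki", "=", 50.0, "nM", None, 2002),
            ("M2", "T1", "Ki", "<", 200.0, "nM", None, 2003),
            ("M3", "T1", "Ki", ">", 10000.0, "nM", None, 2001),
        ])
        first = curate_activities(raw).curated
        # express the curated output as raw records again
        rows = []
        for r in first.itertuples(index=False):
            if r.provenance == "inactive_by_relation":
                rows.append((r.molecule_id, r.target_id, "Ki", ">",
                             10000.0, "nM", None, 2010))
            else:
                rows.append((r.molecule_id, r.target_id, "Ki", "=",
                             r.ki_nM, "nM", None, 2010))
        second = curate_activities(raw_frame(rows)).curated
        merged = first.merge(second, on=["molecule_id", "target_id"],
                             suffixes=("_1", "_2"))
        assert len(merged) == len(first)
        assert np.allclose(merged["spki_1"], merged["spki_2"])


class TestFilterTargets:
    def make_curated(self, spec):
        rows = []
        for tgt, labels in spec.items():
            for i, s in enumerate(labels):
                rows.append(dict(molecule_id=f"{tgt}_M{i}", target_id=tgt,
                                 ki_nM=100.0, spki=s, provenance="measured"))
        return pd.DataFrame(rows)

    def test_thresholds(self):
        rng = np.random.default_rng(0)
        curated = self.make_curated({
            "small": [0.5] * 39,                       # below 40 activities
            "flat": [0.0] * 100,                       # zero spread
            "good": list(rng.uniform(0.1, 0.9, 40)),   # passes both
        })
        kept, report = filter_targets(curated, min_activities=40)
        assert set(kept["target_id"]) == {"good"}
        reasons = dict(zip(report["target_id"], report["reason"]))
        assert "fewer" in reasons["small"]
        assert "variability" in reasons["flat"]

    def test_empty_survivors_rejected(self):
        curated = self.make_curated({"only": [0.5] * 10})
        with pytest.raises(ValueError):
            filter_targets(curated, min_activities=40)
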