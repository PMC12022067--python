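"""Derived clinical scores and binarization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cogdecline import (
    binarize_cohort,
    binarize_record,
    default_feature_definitions,
    lateralized_subscores,
    moca_domain_subscores,
    pigd_tremor_phenotype,
)
from cogdecline.errors import ConfigurationError
from cogdecline.features import (
    AKINESIA_ITEMS,
    LATERAL_TREMOR_ITEMS,
    MOCA_DOMAINS,
    PIGD_ITEMS,
    RIGIDITY_ITEMS,
    TREMOR_SCORE_ITEMS,
    FeatureDefinition,
)

ALL_UPDRS3 = sorted(
    set(
        RIGIDITY_ITEMS["left"] + RIGIDITY_ITEMS["right"]
        + AKINESIA_ITEMS["left"] + AKINESIA_ITEMS["right"]
        + LATERAL_TREMOR_ITEMS["left"] + LATERAL_TREMOR_ITEMS["right"]
        + PIGD_ITEMS + TREMOR_SCORE_ITEMS
    )
)


def _defs_by_name():
    return {d.name: d for d in default_feature_definitions()}


class TestLateralizedSubscores:
    def test_right_rigidity_exceeds_cutoff(self):
        items = dict.fromkeys(ALL_UPDRS3, 0)
        items["updrs3_rigidity_rue"] = 3
        items["updrs3_rigidity_rle"] = 3
        scores = lateralized_subscores(items)
        assert scores["rigidity_right"] == 6
        d = _defs_by_name()["right_rigidity_high"]
        assert d.is_present(scores["rigidity_right"])  # 6 > 5

    def test_all_zero(self):
        scores = lateralized_subscores(dict.fromkeys(ALL_UPDRS3, 0))
        assert all(v == 0 for v in scores.values())

    @given(st.integers(0, 2**32 - 1))
    def test_matches_bruteforce_resummation(self, seed):
        rng = np.random.default_rng(seed)
        items = {k: int(rng.integers(0, 5)) for k in ALL_UPDRS3}
        scores = lateralized_subscores(items)
        for domain, groups in (
            ("rigidity", RIGIDITY_ITEMS),
            ("akinesia", AKINESIA_ITEMS),
            ("tremor", LATERAL_TREMOR_ITEMS),
        ):
            left = sum(items[k] for k in groups["left"])
            right = sum(items[k] for k in groups["right"])
            assert scores[f"{domain}_left"] == left
            assert scores[f"{domain}_right"] == right
            assert scores[f"{domain}_unilateral"] == (left + right) / 2

    def test_missing_constituent_propagates(self):
        items = dict.fromkeys(ALL_UPDRS3, 1)
        items["updrs3_rigidity_rue"] = None
        scores = lateralized_subscores(items)
        assert scores["rigidity_right"] is None
        assert scores["rigidity_unilateral"] is None
        assert scores["rigidity_left"] == 2
        # derived-missing binarizes to absent
        d = _defs_by_name()["right_rigidity_high"]
        assert not d.is_present(scores["rigidity_right"])

    @given(st.integers(0, 2**32 - 1))
    def test_subscore_ranges(self, seed):
        rng = np.random.default_rng(seed)
        items = {k: int(rng.integers(0, 5)) for k in ALL_UPDRS3}
        scores = lateralized_subscores(items)
        assert 0 <= scores["rigidity_left"] <= 8
        assert 0 <= scores["rigidity_right"] <= 8
        assert 0 <= scores["akinesia_left"] <= 20
        assert 0 <= scores["akinesia_right"] <= 20
        pigd, tremor, _ = pigd_tremor_phenotype(items)
        assert 0 <= pigd <= 4 and 0 <= tremor <= 4


class TestPhenotype:
    def test_ratio_one_is_pigd(self):
        items = dict.fromkeys(ALL_UPDRS3, 1)
        pigd, tremor, phenotype = pigd_tremor_phenotype(items)
        assert pigd == tremor == 1.0
        assert phenotype == "pigd"  # ratio <= 1.0

    def test_ratio_three_is_tremor_dominant(self):
        items = dict.fromkeys(ALL_UPDRS3, 0)
        for k in PIGD_ITEMS:
            items[k] = 1
        for k in TREMOR_SCORE_ITEMS:
            items[k] = 3
        _, _, phenotype = pigd_tremor_phenotype(items)
        assert phenotype == "tremor_dominant"

    def test_all_zero_indeterminate(self):
        assert pigd_tremor_phenotype(dict.fromkeys(ALL_UPDRS3, 0))[2] == (
            "indeterminate"
        )

    def test_zero_pigd_with_tremor_is_tremor_dominant(self):
        items = dict.fromkeys(ALL_UPDRS3, 0)
        items["updrs3_rest_tremor_rue"] = 2
        assert pigd_tremor_phenotype(items)[2] == "tremor_dominant"

    def test_intermediate_ratio(self):
        items = dict.fromkeys(ALL_UPDRS3, 0)
        for k in PIGD_ITEMS:
            items[k] = 2
        for k in TREMOR_SCORE_ITEMS:
            items[k] = 3  # ratio 1.5 exactly -> tremor dominant
        assert pigd_tremor_phenotype(items)[2] == "tremor_dominant"
        for k in TREMOR_SCORE_ITEMS:
            items[k] = 2.5  # ratio 1.25 -> neither rule
        assert pigd_tremor_phenotype(items)[2] == "indeterminate"


class TestMocaDomains:
    MAXIMA = {
        "moca_trail": 1, "moca_cube": 1, "moca_clock_contour": 1,
        "moca_clock_numbers": 1, "moca_clock_hands": 1, "moca_naming_lion": 1,
        "moca_naming_rhino": 1, "moca_naming_camel": 1,
        "moca_digits_forward": 1, "moca_digits_backward": 1,
        "moca_vigilance": 1, "moca_serial7": 3, "moca_repetition": 2,
        "moca_fluency": 1, "moca_abstraction": 2, "moca_recall": 5,
        "moca_orientation": 6,
    }

    def test_full_score(self):
        sums = moca_domain_subscores(self.MAXIMA)
        assert sums["visuospatial_executive"] == 5
        assert sum(sums.values()) == 30
        d = _defs_by_name()["visuospatial_executive_low"]
        assert not d.is_present(sums["visuospatial_executive"])

    def test_low_visuospatial_triggers_feature(self):
        items = dict(self.MAXIMA)
        items.update(
            moca_trail=0, moca_cube=0, moca_clock_contour=1,
            moca_clock_numbers=1, moca_clock_hands=0,
        )
        sums = moca_domain_subscores(items)
        assert sums["visuospatial_executive"] == 2
        assert _defs_by_name()["visuospatial_executive_low"].is_present(2)

    @given(st.integers(0, 2**32 - 1))
    def test_regroup_and_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        items = {k: int(rng.integers(0, hi + 1)) for k, hi in self.MAXIMA.items()}
        sums = moca_domain_subscores(items)
        for domain, names in MOCA_DOMAINS.items():
            assert sums[domain] == sum(items[n] for n in names)

    def test_unknown_item_rejected(self):
        with pytest.raises(ConfigurationError):
            moca_domain_subscores({"moca_sudoku": 1})


class TestBinarize:
    @pytest.mark.parametrize(
        "sex, upsit, expected",
        [
            ("female", 30, True),  # 30 < 31
            ("male", 30, False),  # not < 30 (boundary)
            ("female", 31, False),
            ("male", 29, True),
            ("male", None, False),  # missing -> absent
        ],
    )
    def test_sex_specific_upsit(self, sex, upsit, expected):
        d = _defs_by_name()["upsit_low"]
        assert d.is_present(upsit, sex=sex) is expected

    def test_binarize_record_is_total(self):
        defs = default_feature_definitions()
        record = {d.source: None for d in defs}
        record["sex"] = "female"
        vec = binarize_record(record, defs)
        assert vec.shape == (len(defs),)
        assert not vec.any()  # everything missing -> all absent

    def test_unknown_source_is_configuration_error(self):
        d = FeatureDefinition(name="x", source="nonexistent", comparator="gt",
                              cutoff=1)
        with pytest.raises(ConfigurationError):
            binarize_record({"sex": "male"}, [d])

    def test_cohort_binarization_with_derived_scores(self):
        base = dict.fromkeys(ALL_UPDRS3, 0)
        row_hi = dict(base, updrs3_rigidity_rue=4, updrs3_rigidity_rle=3)
        row_lo = dict(base, updrs3_rigidity_rue=2, updrs3_rigidity_rle=2)
        df = pd.DataFrame([row_hi, row_lo])
        df["sex"] = ["male", "female"]
        d = _defs_by_name()["right_rigidity_high"]
        presence = binarize_cohort(df, [d])
        assert list(presence[d.name]) == [True, False]

    @given(
        value=st.floats(-50, 50, allow_nan=False),
        bump=st.floats(0, 20, allow_nan=False),
    )
    def test_gt_monotone(self, value, bump):
        d = FeatureDefinition(name="m", source="v", comparator="gt", cutoff=3.0)
        if d.is_present(value):
            assert d.is_present(value + bump)

    def test_flag_rejects_cutoff(self):
        with pytest.raises(ConfigurationError):
            FeatureDefinition(name="f", source="s", comparator="flag", cutoff=1)

    def test_packaged_battery_has_22_features(self):
        defs = default_feature_definitions()
        assert len(defs) == 22
        assert len({d.name for d in defs}) == 22
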