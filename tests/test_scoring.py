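import numpy as np
import pandas as pd
import pytest

from owod import (
    CohortTable,
    REFERENCE_FEATURES,
    REFERENCE_RECORDS,
    aggregate,
    balanced_class_entropy,
    binary_entropy,
    classify,
    cutoff_owod,
    feature_distances,
    feature_weights,
    information_gain,
    normalize_components,
    owod_components,
    score_cohort,
    score_record,
    split_information,
)
from owod.objective import FeatureParams, ObjectiveParams
from owod.scoring import gain_ratio

from .oracle import oracle_owod

# Score of the eight-feature threshold pseudo-record (5 % below each target),
# frozen from the independent straight-line oracle.
FROZEN_CUTOFF = 0.6139749836552445


class TestFeatureDistances:
    def test_weight_feature_of_reference_record(self):
        d = feature_distances(65.0, 55.0, 90.0)
        assert d.dtc == 10.0
        assert d.dta == 35.0
        assert d.ndtc == pytest.approx(11.111, abs=1e-3)
        assert d.ndta == pytest.approx(38.889, abs=1e-3)
        assert d.rtc == pytest.approx(2 / 9)
        assert d.rta == pytest.approx(7 / 9)

    def test_current_equals_target(self):
        d = feature_distances(130.0, 130.0, 280.0)
        assert d.dtc == 0.0
        assert d.rtc == 0.0
        assert d.rta == 1.0

    def test_fbs_ratio_exact(self):
        d = feature_distances(120.0, 130.0, 280.0)
        assert d.rtc == pytest.approx(10 / 160)

    def test_ratio_is_divisor_free(self, rng):
        """rTC algebraically reduces to dTC/(dTC+dTA), independent of Ai."""
        for _ in range(100):
            c, t = rng.uniform(1, 200, 2)
            a = rng.uniform(1, 300)
            d = feature_distances(c, t, a)
            raw = abs(t - c) + abs(t - a)
            if raw > 0:
                assert d.rtc == pytest.approx(abs(t - c) / raw)

    def test_non_positive_divisor_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            feature_distances(1.0, 2.0, 0.0)


class TestEntropyAndGain:
    def test_maximum_entropy(self):
        assert binary_entropy(0.5, 0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "p,expected",
        [(2 / 9, 0.76), (10 / 160, 0.34), (1 / 3, 0.92), (10 / 35, 0.86)],
    )
    def test_reference_entropies_at_two_decimals(self, p, expected):
        assert round(binary_entropy(p, 1 - p), 2) == pytest.approx(expected, abs=0.01)

    def test_zero_probability_convention(self):
        assert binary_entropy(0.0, 1.0) == 0.0

    def test_non_complementary_rejected(self):
        with pytest.raises(ValueError):
            binary_entropy(0.6, 0.6)

    @pytest.mark.parametrize("na", [2, 8, 20])
    def test_balanced_class_entropy_is_one(self, na):
        epc, oc, nc = balanced_class_entropy(na)
        assert epc == 1.0
        assert oc == nc == na / 2

    def test_information_gain_reference(self, ref_params):
        h = [
            binary_entropy(
                feature_distances(
                    REFERENCE_RECORDS[0][f], ref_params[f].tmi, ref_params[f].ai
                ).rtc,
                feature_distances(
                    REFERENCE_RECORDS[0][f], ref_params[f].tmi, ref_params[f].ai
                ).rta,
            )
            for f in REFERENCE_FEATURES
        ]
        igca, gain = information_gain(np.array(h))
        assert round(igca, 2) == pytest.approx(0.84, abs=0.01)
        assert round(gain, 2) == pytest.approx(0.16, abs=0.01)

    def test_uninformative_features_zero_gain(self):
        igca, gain = information_gain(np.ones(5))
        assert igca == 1.0
        assert gain == 0.0


class TestSplitInformation:
    def test_uniform_split(self):
        assert split_information([5, 5]) == pytest.approx(1.0)

    def test_single_category_zero(self):
        assert split_information([10]) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            gain_ratio(0.5, split_information([10]))

    def test_matches_direct_summation(self):
        counts = [1, 2, 3]
        total = sum(counts)
        expected = -sum(c / total * np.log2(c / total) for c in counts)
        assert split_information(counts) == pytest.approx(expected, abs=1e-12)

    def test_gain_ratio(self):
        assert gain_ratio(0.5, 1.0) == 0.5


class TestWeights:
    def test_equal_entropies_give_uniform_weights(self):
        w = feature_weights(np.full(4, 0.7), gain=0.3)
        np.testing.assert_allclose(w, 0.25)

    def test_reference_weights(self, ref_params):
        res = score_record(REFERENCE_RECORDS[0], ref_params, REFERENCE_FEATURES)
        expected = {
            "W": 0.11, "SBP": 0.14, "DBP": 0.13, "FBS": 0.05,
            "TGS": 0.15, "TC": 0.13, "HDL": 0.15, "LDL": 0.15,
        }
        for f, w in expected.items():
            assert round(res.weights[f], 2) == pytest.approx(w, abs=0.01)
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_non_positive_gain_rejected(self):
        with pytest.raises(ValueError, match="signal"):
            feature_weights(np.ones(3), gain=0.0)


class TestComponentsAndAggregation:
    def test_reference_components(self, ref_params):
        res = score_record(REFERENCE_RECORDS[0], ref_params, REFERENCE_FEATURES)
        expected = {
            "W": 3.15, "SBP": 1.44, "DBP": 1.75, "FBS": 2.50,
            "TGS": 0.46, "TC": 1.75, "HDL": 1.05, "LDL": 0.0,
        }
        for f, c in expected.items():
            assert res.components[f] == pytest.approx(c, abs=0.01)

    def test_symmetric_feature_nullity(self):
        # dTC == dTA (the LDL case) must give a zero component
        comp = owod_components(np.array([0.2]), np.array([18.18]), np.array([18.18]))
        assert comp[0] == 0.0

    def test_reference_normalized_components(self, ref_params):
        res = score_record(REFERENCE_RECORDS[0], ref_params, REFERENCE_FEATURES)
        expected = {
            "W": 1.00, "SBP": 0.46, "DBP": 0.55, "FBS": 0.79,
            "TGS": 0.15, "TC": 0.55, "HDL": 0.33, "LDL": 0.0,
        }
        for f, v in expected.items():
            assert res.normalized[f] == pytest.approx(v, abs=0.01)

    def test_degenerate_normalization(self):
        norm, flag = normalize_components(np.full(6, 2.2))
        assert flag
        np.testing.assert_allclose(norm, 0.5)

    def test_aggregate_is_mean(self, rng):
        v = rng.uniform(0, 1, 50)
        assert aggregate(v) == pytest.approx(v.mean(), abs=1e-12)
        assert aggregate(np.zeros(4)) == 0.0

    def test_reference_owod(self, ref_params):
        res = score_record(REFERENCE_RECORDS[0], ref_params, REFERENCE_FEATURES)
        assert res.owod == pytest.approx(0.48, abs=0.01)


class TestScoreRecord:
    def test_boundary_record_all_at_acceptable(self, ref_params):
        values = {f: ref_params[f].ai for f in REFERENCE_FEATURES}
        res = score_record(values, ref_params, REFERENCE_FEATURES)
        assert res.degenerate
        assert res.owod == pytest.approx(0.5)
        assert all(c == pytest.approx(0.0) for c in res.components.values())

    def test_missing_value_rejected(self, ref_params):
        values = dict(REFERENCE_RECORDS[0])
        values["W"] = float("nan")
        with pytest.raises(ValueError, match="'W'"):
            score_record(values, ref_params, REFERENCE_FEATURES)

    def test_oracle_equivalence_on_random_records(self, ref_params, rng):
        """Chain agrees with the independent reimplementation to 1e-9."""
        feats = REFERENCE_FEATURES
        t = [ref_params[f].tmi for f in feats]
        a = [ref_params[f].ai for f in feats]
        for _ in range(1000):
            vals = [float(rng.uniform(0.3 * ti, 2.5 * ti)) for ti in t]
            res = score_record(dict(zip(feats, vals)), ref_params, feats)
            assert res.owod == pytest.approx(oracle_owod(vals, t, a), abs=1e-9)

    def test_vectorized_matches_scalar_path(self, ref_params, rng):
        feats = REFERENCE_FEATURES
        n = 200
        data = pd.DataFrame(
            {f: rng.uniform(0.3 * ref_params[f].tmi, 2.5 * ref_params[f].tmi, n)
             for f in feats},
            index=pd.Index([str(i) for i in range(n)], name="id"),
        )
        cohort = CohortTable(data=data)
        scored = score_cohort(cohort, ref_params, feats)
        for i in range(n):
            res = score_record(data.iloc[i].to_dict(), ref_params, feats)
            assert scored["owod"].iloc[i] == pytest.approx(res.owod, abs=1e-12)
            assert scored[f"w_W"].iloc[i] == pytest.approx(res.weights["W"], abs=1e-12)


class TestCutoff:
    def test_frozen_regression_value(self, ref_params):
        cut = cutoff_owod(ref_params, REFERENCE_FEATURES)
        assert cut.owod_c == pytest.approx(FROZEN_CUTOFF, abs=1e-12)

    def test_rescoring_provenance_reproduces_cutoff(self, ref_params):
        cut = cutoff_owod(ref_params, REFERENCE_FEATURES)
        res = score_record(cut.pseudo_record, ref_params, REFERENCE_FEATURES)
        assert res.owod == cut.owod_c

    def test_direction_symmetry(self):
        """5 % above and 5 % below the target give the same cut-off score."""
        below = ObjectiveParams({
            "x": FeatureParams(100.0, 150.0, 95.0),
            "y": FeatureParams(80.0, 60.0, 76.0),
        })
        above = ObjectiveParams({
            "x": FeatureParams(100.0, 150.0, 105.0),
            "y": FeatureParams(80.0, 60.0, 84.0),
        })
        assert cutoff_owod(below).owod_c == pytest.approx(cutoff_owod(above).owod_c)

    def test_degenerate_pseudo_record_rejected(self):
        params = ObjectiveParams({
            "x": FeatureParams(100.0, 150.0, 100.0),
            "y": FeatureParams(80.0, 60.0, 76.0),
        })
        with pytest.raises(ValueError, match="degenerate"):
            cutoff_owod(params)


class TestClassify:
    @pytest.mark.parametrize(
        "owod,cut,positive",
        [(0.48, 0.56, True), (0.56, 0.56, True), (0.561, 0.56, False)],
    )
    def test_rule_with_inclusive_tie(self, owod, cut, positive):
        assert classify(owod, cut) is positive

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify(float("nan"), 0.5)
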