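import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import fbeta_score

from conftest import make_messages
from darkgaps.gap_classifier import (EXCLUDED, NOT_SUSPECTED, RETAINED,
                                     SUSPECTED, ClassifierEval, GapError,
                                     RuleModel, classify, detect_gaps,
                                     default_candidate_grid, evaluate,
                                     f_beta, filter_gaps, label_gaps,
                                     select_model)
from darkgaps.grid import GridSpec, Raster
from darkgaps.reception import ReceptionGrid


def _flat_raster(value, west=-40, south=-30, size=20, cell=1.0):
    spec = GridSpec(west, south, west + size, south + size, cell)
    return Raster(spec, np.full(spec.shape, float(value)))


def _reception(value, **kw):
    return ReceptionGrid(_flat_raster(value, **kw), "A", "predicted")


def _fake_gaps(pings_12h, truth, reception=25.0, duration=30.0):
    """Synthetic retained-gap table for model-selection tests."""
    n = len(pings_12h)
    return pd.DataFrame({
        "vessel_id": [f"v{i}" for i in range(n)],
        "start_time": pd.Timestamp("2018-01-01", tz="UTC"),
        "end_time": pd.Timestamp("2018-01-02", tz="UTC"),
        "duration_h": duration, "start_lon": -35.0, "start_lat": -25.0,
        "end_lon": -35.0, "end_lat": -25.0, "device_class": "A",
        "gear": "trawler", "flag": "CHN",
        "pings_6h": np.asarray(pings_12h) // 2,
        "pings_12h": pings_12h, "pings_18h": pings_12h,
        "pings_24h": pings_12h,
        "dist_shore_nmi": 200.0, "reception_pred": reception,
        "classification": RETAINED, "truth": truth})


class TestDetectGaps:
    def test_below_threshold_no_gap(self):
        gaps = detect_gaps(make_messages([0.0, 11.0]))
        assert len(gaps) == 0

    def test_exact_boundary_11_99_vs_12(self):
        assert len(detect_gaps(make_messages([0.0, 11.99]))) == 0
        assert len(detect_gaps(make_messages([0.0, 12.0]))) == 1

    def test_lookback_count_half_open_window(self):
        # pings at 0..12 h then 36 h: one 24 h gap starting at t=12;
        # the half-open window (0, 12] holds the 12 pings at 1..12 (the
        # boundary ping at the gap start counts, the one at t=0 does not)
        gaps = detect_gaps(make_messages(list(range(13)) + [36.0]))
        assert len(gaps) == 1
        g = gaps.iloc[0]
        assert g["duration_h"] == pytest.approx(24.0)
        assert g["pings_12h"] == 12

    def test_planted_gap_endpoints(self):
        times = [0, 2, 4, 6, 54, 56]
        lons = [-35.0, -35.1, -35.2, -35.3, -34.0, -34.1]
        gaps = detect_gaps(make_messages(times, lons=lons,
                                         lats=np.full(6, -25.0)))
        assert len(gaps) == 1
        g = gaps.iloc[0]
        assert g["duration_h"] == pytest.approx(48.0)
        assert g["start_lon"] == -35.3 and g["end_lon"] == -34.0

    def test_single_message_vessel_yields_nothing(self):
        assert len(detect_gaps(make_messages([5.0]))) == 0

    def test_vessel_independence(self):
        m1 = make_messages([0, 1, 30], vessel_id="a")
        m2 = make_messages([0, 20, 21], vessel_id="b")
        combined = detect_gaps(pd.concat([m1, m2]))
        separate = pd.concat([detect_gaps(m1), detect_gaps(m2)],
                             ignore_index=True)
        pd.testing.assert_frame_equal(combined, separate)


class TestFilterGaps:
    def _one_gap(self):
        return detect_gaps(make_messages([0.0] + list(range(1, 13)) + [40.0],
                                         lons=np.full(14, -25.0),
                                         lats=np.full(14, -25.0)))

    def test_reception_exactly_10_excluded(self):
        out = filter_gaps(self._one_gap(), _flat_raster(400), _reception(10.0))
        assert (out["classification"] == EXCLUDED).all()

    def test_shore_just_inside_50nmi_excluded(self):
        # 49.9 nmi from shore, good reception: still excluded
        out = filter_gaps(self._one_gap(), _flat_raster(49.9 * 1.852),
                          _reception(25.0))
        assert (out["classification"] == EXCLUDED).all()

    def test_shore_exactly_50nmi_excluded(self):
        out = filter_gaps(self._one_gap(), _flat_raster(50.0 * 1.852),
                          _reception(25.0))
        assert (out["classification"] == EXCLUDED).all()

    def test_open_water_good_reception_retained(self):
        out = filter_gaps(self._one_gap(), _flat_raster(120 * 1.852),
                          _reception(25.0))
        assert (out["classification"] == RETAINED).all()
        assert out["dist_shore_nmi"].iloc[0] == pytest.approx(120.0)

    def test_outside_extent_names_vessel(self):
        with pytest.raises(GapError, match="900000001"):
            filter_gaps(self._one_gap(), _flat_raster(100, west=0, south=0),
                        _reception(25.0, west=0, south=0))


class TestClassify:
    def _retained(self, pings):
        gaps = _fake_gaps([pings], ["intentional"])
        return gaps

    def test_default_model_suspects_high_ping_rate(self):
        out = classify(self._retained(20), RuleModel(12, 14))
        assert out["classification"].iloc[0] == SUSPECTED

    def test_k_boundary(self):
        assert classify(self._retained(14), RuleModel(12, 14)) \
            ["classification"].iloc[0] == SUSPECTED
        assert classify(self._retained(13), RuleModel(12, 14)) \
            ["classification"].iloc[0] == NOT_SUSPECTED

    def test_k_one_degenerate(self):
        out = classify(self._retained(1), RuleModel(12, 1))
        assert out["classification"].iloc[0] == SUSPECTED

    def test_monotone_in_k(self):
        rng = np.random.default_rng(0)
        gaps = _fake_gaps(rng.integers(0, 40, 200),
                          ["intentional"] * 200)
        prev = None
        for k in range(1, 30):
            sus = set(classify(gaps, RuleModel(12, k)).query(
                "classification == @SUSPECTED").index)
            if prev is not None:
                assert sus <= prev
            prev = sus

    def test_missing_lookback_errors(self):
        gaps = _fake_gaps([5], ["intentional"]).drop(columns=["pings_18h"])
        with pytest.raises(GapError):
            classify(gaps, RuleModel(18, 5))


class TestFBeta:
    def test_perfect(self):
        assert f_beta(10, 0, 0) == 1.0

    def test_zero_tp(self):
        assert f_beta(0, 5, 5) == 0.0

    def test_hand_computed_example(self):
        # P = 0.8, R = 0.5 -> 1.25 * 0.4 / 0.7
        assert f_beta(40, 10, 40) == pytest.approx(0.714286, abs=1e-6)

    def test_all_zero_undefined(self):
        with pytest.raises(GapError):
            f_beta(0, 0, 0)

    def test_matches_per_item_oracle(self):
        # 1,000 random label sets vs sklearn's per-item F-beta
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(2, 60)
            y = rng.integers(0, 2, n)
            p = rng.integers(0, 2, n)
            tp = int(((y == 1) & (p == 1)).sum())
            fp = int(((y == 0) & (p == 1)).sum())
            fn = int(((y == 1) & (p == 0)).sum())
            if tp + fp + fn == 0:
                continue
            expect = fbeta_score(y, p, beta=0.5, zero_division=0)
            assert f_beta(tp, fp, fn) == pytest.approx(expect, abs=1e-12)


class TestEvaluate:
    def test_all_correct(self):
        gaps = classify(_fake_gaps([20] * 5 + [0] * 5,
                                   ["intentional"] * 5 + ["reception"] * 5),
                        RuleModel(12, 14))
        ev = evaluate(gaps)
        assert ev.precision == 1.0 and ev.fpr == 0.0

    def test_hand_confusion_rates(self):
        ev = ClassifierEval(tp=86, fp=14, fn=50, tn=350)
        assert ev.precision == pytest.approx(0.86)
        assert ev.fpr == pytest.approx(14 / 364, abs=1e-6)

    def test_no_positives_precision_missing(self):
        gaps = classify(_fake_gaps([0, 0], ["intentional", "reception"]),
                        RuleModel(12, 14))
        ev = evaluate(gaps)
        assert ev.precision is None


class TestLabelGaps:
    def test_nested_interval_marks_intentional(self):
        gaps = detect_gaps(make_messages([0, 1, 2, 40]))
        truth = pd.DataFrame({
            "vessel_id": ["900000001"], "cause": ["intentional"],
            "start": [pd.Timestamp("2018-01-01 02:00", tz="UTC")],
            "end": [pd.Timestamp("2018-01-02 16:00", tz="UTC")],
            "start_lon": -35.1, "start_lat": -25.1,
            "end_lon": -35.1, "end_lat": -25.1})
        out = label_gaps(gaps, truth)
        assert out["truth"].iloc[0] == "intentional"

    def test_unmatched_gap_is_reception(self):
        gaps = detect_gaps(make_messages([0, 1, 2, 40]))
        out = label_gaps(gaps, pd.DataFrame(
            columns=["vessel_id", "start", "end", "cause"]))
        assert out["truth"].iloc[0] == "reception"


class TestSelectModel:
    def test_single_candidate_returned(self):
        gaps = _fake_gaps([20] * 10 + [2] * 10,
                          ["intentional"] * 10 + ["reception"] * 10)
        only = RuleModel(12, 25)
        best, table, _ = select_model(gaps, [only], seed=0)
        assert best == only

    def test_perfect_separator_selected_with_f05_one(self):
        gaps = _fake_gaps([30] * 20 + [2] * 20,
                          ["intentional"] * 20 + ["reception"] * 20)
        grid = [RuleModel(12, 10), RuleModel(12, 35)]
        best, table, ev = select_model(gaps, grid, seed=1)
        assert best == RuleModel(12, 10)
        assert table["mean_f05"].max() == pytest.approx(1.0)
        assert ev.precision == 1.0

    def test_tie_broken_by_smaller_k(self):
        # both candidates classify identically -> identical scores
        gaps = _fake_gaps([30] * 20 + [0] * 20,
                          ["intentional"] * 20 + ["reception"] * 20)
        best, _, _ = select_model(gaps, [RuleModel(12, 6), RuleModel(12, 5)],
                                  seed=2)
        assert best.k == 5

    def test_fold_assignment_reproducible(self):
        rng = np.random.default_rng(3)
        gaps = _fake_gaps(rng.integers(0, 40, 80),
                          list(rng.choice(["intentional", "reception"], 80)))
        grid = default_candidate_grid(ks=range(2, 10))
        b1, t1, _ = select_model(gaps, grid, seed=5)
        b2, t2, _ = select_model(gaps, grid, seed=5)
        assert b1 == b2
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_class_truth_errors(self):
        gaps = _fake_gaps([20] * 10, ["intentional"] * 10)
        with pytest.raises(GapError):
            select_model(gaps, [RuleModel(12, 5)], seed=0)
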