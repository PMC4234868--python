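import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedprobe import reference, thresholds
from pedprobe.errors import (
    DegenerateBandError,
    IncompleteLabelingError,
    InvalidParameterError,
)


def labeled_series(rng=None, n_per=5, means=None):
    """Small well-separated labeled factor table."""
    rng = rng or np.random.default_rng(0)
    means = means or {
        "spongy": dict(mu_s_reduced=17.0, peak=880.0, area=185000.0, slope=15.0),
        "alarm": dict(mu_s_reduced=14.7, peak=640.0, area=107000.0, slope=3.0),
        "compact": dict(mu_s_reduced=12.8, peak=464.0, area=72000.0, slope=1.8),
    }
    rows = []
    depth = 0.0
    for region, m in means.items():
        for _ in range(n_per):
            rows.append(
                {
                    "depth_mm": depth,
                    "region": region,
                    **{k: v * (1 + 0.01 * rng.standard_normal()) for k, v in m.items()},
                }
            )
            depth += 0.2
    return pd.DataFrame(rows)


class TestSummarizeRegions:
    def test_single_record_mean_equals_extremes(self):
        df = labeled_series(n_per=1)
        s = thresholds.summarize_regions(df)
        for factor in thresholds.FACTOR_NAMES:
            assert s.value("alarm", factor, "mean") == s.value("alarm", factor, "min")
            assert s.value("alarm", factor, "mean") == s.value("alarm", factor, "max")

    def test_label_order_invariance(self):
        df = labeled_series()
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = thresholds.summarize_regions(df).table.sort_index()
        b = thresholds.summarize_regions(shuffled).table.sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_missing_region_rejected(self):
        df = labeled_series()
        with pytest.raises(IncompleteLabelingError):
            thresholds.summarize_regions(df[df.region != "alarm"])


class TestRatioFormulas:
    """Worked examples from the published porcine vertebra aggregates."""

    def test_ratio1(self):
        assert 100 * thresholds.ratio1(185213.61, 106896.1) == pytest.approx(
            42.28, abs=0.005
        )
        assert 100 * thresholds.ratio1(16.91, 14.71) == pytest.approx(13.01, abs=0.005)
        assert thresholds.ratio1(5.0, 5.0) == 0.0

    def test_ratio2(self):
        assert 100 * thresholds.ratio2(106896.1, 72472.75) == pytest.approx(
            32.20, abs=0.005
        )
        assert 100 * thresholds.ratio2(638.5, 463.91) == pytest.approx(27.34, abs=0.005)

    def test_ratio3_and_overlap_sign(self):
        assert 100 * thresholds.ratio3(170300.3, 129871.7) == pytest.approx(
            23.74, abs=0.005
        )
        assert 100 * thresholds.ratio3(825.0, 649.33) == pytest.approx(21.29, abs=0.005)
        assert thresholds.ratio3(100.0, 120.0) < 0  # overlap flagged by sign

    def test_ratio4(self):
        assert 100 * thresholds.ratio4(597.0, 503.33) == pytest.approx(15.69, abs=0.005)
        assert 100 * thresholds.ratio4(89782.84, 80788.38) == pytest.approx(
            10.02, abs=0.005
        )
        assert thresholds.ratio4(5.0, 5.0) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(InvalidParameterError):
            thresholds.ratio1(0.0, 1.0)

    @given(c=st.floats(min_value=1e-3, max_value=1e6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        base = thresholds.ratio1(170.0, 130.0)
        assert thresholds.ratio1(170.0 * c, 130.0 * c) == pytest.approx(
            base, rel=1e-9
        )
        base3 = thresholds.ratio3(170.0, 130.0)
        assert thresholds.ratio3(170.0 * c, 130.0 * c) == pytest.approx(
            base3, rel=1e-9
        )


class TestSelectAlarmFactor:
    def test_published_tables_select_area(self):
        ratios = thresholds.compute_ratios(reference.VERTEBRA_SUMMARY)
        sel = thresholds.select_alarm_factor(ratios)
        assert sel.factor == "area"

    def test_dominant_factor_wins(self):
        frac = pd.DataFrame(
            {
                "mu_s_reduced": [0.1, 0.1, 0.1, 0.1],
                "peak": [0.2, 0.2, 0.2, 0.2],
                "area": [0.9, 0.9, 0.9, 0.9],
                "slope": [0.3, 0.3, 0.3, 0.3],
            },
            index=list(thresholds.RATIO_NAMES),
        )
        valid = frac.notna()
        sel = thresholds.select_alarm_factor(thresholds.RatioTable(frac, valid))
        assert sel.factor == "area"

    def test_tie_breaks_by_name(self):
        frac = pd.DataFrame(
            {
                "mu_s_reduced": [0.1] * 4,
                "peak": [0.9] * 4,
                "area": [0.9] * 4,
                "slope": [0.1] * 4,
            },
            index=list(thresholds.RATIO_NAMES),
        )
        sel = thresholds.select_alarm_factor(thresholds.RatioTable(frac, frac.notna()))
        assert sel.factor == "area"  # 'area' < 'peak' alphabetically


class TestAlarmBand:
    def test_published_alarm_area_band(self):
        band = thresholds.alarm_band(reference.VERTEBRA_SUMMARY, "area")
        assert (band.lower, band.upper) == (89783, 129872)

    def test_degenerate_band_rejected(self):
        with pytest.raises(DegenerateBandError):
            thresholds.AlarmBand("area", 5.0, 5.0)

    def test_round_half_up(self):
        assert thresholds.round_half_up(89782.84) == 89783
        assert thresholds.round_half_up(129871.7) == 129872
        assert thresholds.round_half_up(2.5) == 3
        assert thresholds.round_half_up(2.49) == 2


class TestClassifyPoint:
    def setup_method(self):
        self.band = thresholds.AlarmBand("area", 89783, 129872)

    @pytest.mark.parametrize(
        "value,label",
        [
            (100000.0, "alarm"),
            (185213.61, "spongy"),
            (72472.75, "compact"),
            (89783.0, "alarm"),   # endpoints belong to alarm
            (129872.0, "alarm"),
            (129872.1, "spongy"),
        ],
    )
    def test_partition(self, value, label):
        assert thresholds.classify_point(value, self.band) == label

    @given(v=st.floats(min_value=0, max_value=3e5, allow_nan=False))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_every_value_gets_exactly_one_label(self, v):
        label = thresholds.classify_point(v, self.band)
        assert label in thresholds.REGIONS


class TestGroupSeparation:
    def test_well_separated_groups_pass(self):
        rep = thresholds.group_separation(labeled_series(n_per=8))
        assert rep.all_passed

    def test_identical_groups_fail(self):
        means = {r: dict(mu_s_reduced=10.0, peak=1.0, area=1.0, slope=1.0)
                 for r in thresholds.REGIONS}
        df = labeled_series(rng=np.random.default_rng(3), n_per=8, means=means)
        # same generating distribution in every region: should not separate
        rep = thresholds.group_separation(df)
        assert not rep.all_passed

    def test_permuted_labels_lose_significance(self):
        rng = np.random.default_rng(11)
        df = labeled_series(rng=rng, n_per=8)
        pvals = []
        for _ in range(20):
            perm = df.copy()
            perm["region"] = rng.permutation(perm["region"].to_numpy())
            pvals.append(float(thresholds.group_separation(perm).pvalues["area"]))
        assert np.median(pvals) > 0.05  # permutation null is non-significant


class TestPublishedRatioConsistency:
    def test_inconsistent_cells_are_the_documented_ones(self):
        mism = reference.check_published_ratios()
        cells = {(r, f) for r, f, _, _ in mism}
        assert cells == set(reference.INCONSISTENT_PUBLISHED_RATIOS)
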