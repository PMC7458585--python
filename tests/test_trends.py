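"""RSV normalization, peak windows, the APC estimator, spikes and events."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from infodemic.errors import ValidationError
from infodemic.iscale import IScaleResult, classify_severity
from infodemic.trends import (
    ApcEstimate,
    Event,
    PeakObservation,
    RsvSeries,
    aggregate_by_severity,
    align_events,
    compute_apc,
    detect_breakout,
    detect_spikes,
    extract_peaks,
    normalize_rsv,
    rank_by_apc,
)

D0 = dt.date(2020, 2, 20)


def days(n):
    return [D0 + dt.timedelta(days=i) for i in range(n)]


def series(values, normalized=None, geo="GLOBAL"):
    # normalized flag defaults to whatever the values support: a normalized
    # nonzero series must attain 100, so pattern excerpts without a 100 are
    # treated as unnormalized fragments
    if normalized is None:
        normalized = not any(values) or max(values) == 100
    return RsvSeries("kw", geo, tuple(days(len(values))), tuple(values),
                     normalized=normalized, degenerate=all(v == 0 for v in values))


# ---------------------------------------------------------------- normalize

@pytest.mark.parametrize(
    "raw, expected",
    [
        ([50, 100, 25], [50, 100, 25]),   # already scaled
        ([2, 4, 1], [50, 100, 25]),       # linear rescale
        ([3, 7, 9], [33, 78, 100]),       # hand oracle: round_half_up(100 x/9)
    ],
)
def test_normalize_rsv_examples(raw, expected):
    assert list(normalize_rsv(raw).values) == expected


def test_normalize_rsv_degenerate_and_errors():
    s = normalize_rsv([0, 0, 0])
    assert s.degenerate and set(s.values) == {0}
    with pytest.raises(ValidationError):
        normalize_rsv([1, -2])
    with pytest.raises(ValidationError):
        normalize_rsv([])


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=50))
def test_normalize_rsv_order_max_and_idempotence(raw):
    s = normalize_rsv(raw)
    vals = s.values
    if any(raw):
        assert max(vals) == 100
        # order preservation
        for i in range(len(raw)):
            for j in range(len(raw)):
                if raw[i] <= raw[j]:
                    assert vals[i] <= vals[j]
        assert list(normalize_rsv(list(vals)).values) == list(vals)  # idempotent
    else:
        assert s.degenerate


def test_rsv_series_invariants():
    with pytest.raises(ValidationError):
        RsvSeries("k", "g", tuple(days(2)), (5, 101))
    with pytest.raises(ValidationError):
        RsvSeries("k", "g", (D0, D0), (100, 100))
    with pytest.raises(ValidationError):  # normalized nonzero must attain 100
        RsvSeries("k", "g", tuple(days(2)), (10, 20), normalized=True)


# ------------------------------------------------------------------- peaks

def test_extract_peaks_tiles_windows():
    vals = [0, 0, 100, 0, 0, 0, 0, 0, 50, 0, 0, 0, 0, 0]
    peaks = extract_peaks(series(vals), 7)
    assert [(p.window_index, p.peak_value) for p in peaks] == [(0, 100), (1, 50)]


def test_extract_peaks_constant_and_partial_window():
    s = RsvSeries("k", "g", tuple(days(10)), tuple([10] * 10), normalized=False)
    peaks = extract_peaks(s, 7)
    assert [p.peak_value for p in peaks] == [10, 10]  # trailing 3-day window kept
    with pytest.raises(ValidationError):
        extract_peaks(s, 0)


# --------------------------------------------------------------------- APC

def test_compute_apc_zero_variance_and_additivity():
    one = compute_apc([PeakObservation("A", i, 10) for i in range(3)])
    assert (one.total, one.ci_low, one.ci_high) == (10, 10, 10)
    two = compute_apc(
        [PeakObservation("A", 0, 5), PeakObservation("B", 0, 7)]
    )
    assert (two.total, two.ci_low, two.ci_high) == (12, 12, 12)
    with pytest.raises(ValidationError):
        compute_apc([])


def test_compute_apc_k_identical_geos_scale_total():
    rng = np.random.default_rng(0)
    vals = rng.normal(50, 5, 20)
    single = compute_apc([PeakObservation("G", i, v) for i, v in enumerate(vals)])
    k = 4
    multi = compute_apc(
        [PeakObservation(f"G{g}", i, v) for g in range(k) for i, v in enumerate(vals)]
    )
    assert multi.total == pytest.approx(k * single.total)


def test_compute_apc_matches_normal_theory_oracle():
    """Single geography: CI must equal mean +/- z * s/sqrt(n) (scipy oracle)."""
    rng = np.random.default_rng(42)
    vals = rng.normal(50, 5, 200)
    est = compute_apc([PeakObservation("G", i, v) for i, v in enumerate(vals)])
    lo, hi = stats.norm.interval(0.95, loc=vals.mean(), scale=stats.sem(vals))
    assert est.total == pytest.approx(vals.mean())
    assert (est.ci_low, est.ci_high) == (pytest.approx(lo), pytest.approx(hi))


def test_compute_apc_large_sample_point_accuracy():
    rng = np.random.default_rng(20200220)
    vals = rng.normal(50, 5, 10_000)
    est = compute_apc([PeakObservation("G", i, v) for i, v in enumerate(vals)])
    assert abs(est.total - 50) < 0.15  # 3 sigma of the mean at n=10,000


# --------------------------------------------------------- breakout / spikes

def test_detect_breakout():
    s = series([10, 100, 20, 100, 0])
    assert detect_breakout(s) == [D0 + dt.timedelta(days=1), D0 + dt.timedelta(days=3)]
    assert detect_breakout(series([0, 0])) == []
    with pytest.raises(ValidationError):
        detect_breakout(series([10, 50], normalized=False))


def test_normalized_nonzero_series_always_has_breakout():
    for raw in ([3, 7, 9], [1], [5, 5, 5], [0, 2, 0]):
        assert detect_breakout(normalize_rsv(raw))


@pytest.mark.parametrize(
    "vals, threshold, expected_ix",
    [
        ([10, 70, 10], 50, [1]),            # interior spike, e.g. RSV=70
        ([10, 20, 30, 100], 1, [3]),        # monotone: endpoint rule
        ([50, 50, 50, 100], 40, [3]),       # flat stretch never spikes
        ([100, 3, 53, 3], 50, [0, 2]),      # leading endpoint + interior
    ],
)
def test_detect_spikes(vals, threshold, expected_ix):
    s = series(vals)
    got = detect_spikes(s, threshold)
    assert got == [(s.dates[i], vals[i]) for i in expected_ix]


def test_detect_spikes_threshold_validation():
    with pytest.raises(ValidationError):
        detect_spikes(series([100]), 0)


# ------------------------------------------------------------------ events

def test_align_events_exact_tolerance_and_tie():
    spike = (dt.date(2020, 4, 17), 100)
    hit = Event(dt.date(2020, 4, 17), "lab-origin claim")
    res = align_events([spike], [hit], tolerance_days=0)
    assert res.matches[0][1] is hit and not res.unmatched_spikes

    far = align_events([(D0 + dt.timedelta(days=10), 60)],
                       [Event(D0 + dt.timedelta(days=14), "too late")], 2)
    assert far.matches == () and len(far.unmatched_spikes) == 1
    assert len(far.unmatched_events) == 1

    before = Event(dt.date(2020, 4, 16), "earlier")
    after = Event(dt.date(2020, 4, 18), "later")
    tie = align_events([spike], [after, before], tolerance_days=1)
    assert tie.matches[0][1] is before  # equidistant -> earlier event wins


# ----------------------------------------------------------- rank/aggregate

def est(kw, total, var_sum=None):
    return ApcEstimate(kw, total, total, total, 1, var_sum=var_sum)


def test_rank_by_apc_ties_and_truncation():
    ranked = rank_by_apc([est("b", 5), est("a", 5), est("c", 9)], n=2)
    assert [e.keyword for e in ranked] == ["c", "a"]
    assert len(rank_by_apc([est("a", 1)], n=10)) == 1


def sc(kw, score):
    return IScaleResult(kw, score, classify_severity(score))


def test_aggregate_single_keyword_share_one():
    summ = aggregate_by_severity([est("a", 7)], [sc("a", 0)])
    assert summ.classes["not_infodemic"].share == 1.0
    assert all(summ.classes[s].share == 0.0 for s in summ.classes if s != "not_infodemic")


def test_aggregate_totals_and_shares_are_consistent():
    ests = [est(f"k{i}", t, var_sum=1.0) for i, t in enumerate([5, 10, 20, 40, 80])]
    scores = [sc(f"k{i}", s) for i, s in enumerate([0, 1, 3, 6, 9])]
    summ = aggregate_by_severity(ests, scores)
    assert sum(c.total_apc for c in summ.classes.values()) == summ.grand_total == 155
    assert sum(c.share for c in summ.classes.values()) == pytest.approx(1.0, abs=1e-9)
    # every member carries a variance term -> variance-propagated CIs
    assert all(c.ci_method == "variance" for c in summ.classes.values() if c.monikers)


def test_aggregate_falls_back_to_bound_sums_without_variances():
    ests = [ApcEstimate("a", 10, 8, 12, 1), ApcEstimate("b", 20, 17, 24, 1)]
    summ = aggregate_by_severity(ests, [sc("a", 3), sc("b", 4)])
    c = summ.classes["moderately"]
    assert (c.ci_low, c.ci_high, c.ci_method) == (25, 36, "bounds")


def test_aggregate_requires_a_score_per_keyword():
    with pytest.raises(ValidationError, match="without I-scale score"):
        aggregate_by_severity([est("a", 1)], [sc("b", 2)])


def test_ci_halfwidth_scales_as_inverse_sqrt_n():
    """Mean CI width halves (within 15%) when n quadruples: 25 -> 100 -> 400."""
    rng = np.random.default_rng(1)
    mean_width = {}
    for n in (25, 100, 400):
        widths = []
        for _ in range(200):
            vals = rng.normal(50, 5, n)
            e = compute_apc([PeakObservation("G", i, v) for i, v in enumerate(vals)])
            widths.append(e.ci_high - e.ci_low)
        mean_width[n] = np.mean(widths)
    assert mean_width[100] / mean_width[25] == pytest.approx(0.5, rel=0.15)
    assert mean_width[400] / mean_width[100] == pytest.approx(0.5, rel=0.15)
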