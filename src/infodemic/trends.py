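"""Statistics over normalized search-volume (RSV) time series.

Google Trends reports *relative search volume*: for a keyword and geography,
daily search counts rescaled so the busiest day in the window is 100 and
every value is an integer in [0, 100].  This module provides

* :func:`normalize_rsv` — the 0-100 rescaling, half-up rounded;
* :func:`extract_peaks` — windowed peak extraction (default 7-day windows
  anchored at the first observation; a trailing partial window is kept);
* :func:`compute_apc` — the *average peak volume* (APC) estimator: the sum
  over geographies of per-geography mean window peaks, with a Gaussian
  confidence interval by variance propagation.  Totals can exceed 100
  because they are summed across geographies/series;
* :func:`detect_breakout` — dates at the RSV ceiling of 100 ("breakout");
* :func:`detect_spikes` — strict local maxima above a threshold;
* :func:`align_events` — matching spikes to dated news events;
* :func:`rank_by_apc` and :func:`aggregate_by_severity` — ranking keywords
  by APC and pooling APC totals by I-scale severity class.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rounding import round_half_up
from .errors import ValidationError
from .iscale import SEVERITIES, IScaleResult

__all__ = [
    "RsvSeries",
    "PeakObservation",
    "ApcEstimate",
    "Event",
    "SeverityClassSummary",
    "SeveritySummary",
    "EventAlignment",
    "normalize_rsv",
    "extract_peaks",
    "compute_apc",
    "detect_breakout",
    "detect_spikes",
    "align_events",
    "rank_by_apc",
    "aggregate_by_severity",
    "read_series_csv",
    "read_events_csv",
    "estimates_to_frame",
    "plot_series",
]

#: Default study window mirrors the analysis period Feb 20 - May 6, 2020.
STUDY_START = dt.date(2020, 2, 20)
STUDY_END = dt.date(2020, 5, 6)


@dataclass(frozen=True)
class RsvSeries:
    """An integer 0-100 search-volume series for one keyword x geography.

    ``degenerate`` marks an all-zero series (no searches in the window);
    for any other normalized series the maximum is exactly 100.
    """

    keyword: str
    geo: str
    dates: tuple[dt.date, ...]
    values: tuple[int, ...]
    normalized: bool = True
    degenerate: bool = False

    def __post_init__(self):
        if len(self.dates) != len(self.values):
            raise ValidationError("dates and values must have equal length")
        if len(self.dates) == 0:
            raise ValidationError("empty series")
        if any(b <= a for a, b in zip(self.dates, self.dates[1:])):
            raise ValidationError("dates must be strictly increasing")
        if any(not 0 <= v <= 100 for v in self.values):
            raise ValidationError("RSV values must lie in [0, 100]")
        if self.normalized and any(v > 0 for v in self.values) and max(self.values) != 100:
            raise ValidationError("a normalized nonzero series must attain 100")


@dataclass(frozen=True)
class PeakObservation:
    """Maximum RSV inside one tiling window of one geography's series."""

    geo: str
    window_index: int
    peak_value: float


@dataclass(frozen=True)
class ApcEstimate:
    """Average peak volume total with its Gaussian confidence interval.

    ``var_sum`` is the propagated variance term sum_g s_g^2 / n_g; it is
    ``None`` for estimates loaded from printed tables, where only the CI
    bounds are known.
    """

    keyword: str
    total: float
    ci_low: float
    ci_high: float
    n_obs: int
    level: float = 0.95
    var_sum: float | None = None


@dataclass(frozen=True)
class Event:
    """A dated news event hypothesised to drive searches for a keyword."""

    date: dt.date
    label: str
    keyword: str = ""

    def __post_init__(self):
        if not self.label:
            raise ValidationError("event label must be non-empty")


def normalize_rsv(
    raw: Sequence[float],
    dates: Sequence[dt.date] | None = None,
    keyword: str = "",
    geo: str = "GLOBAL",
) -> RsvSeries:
    """Rescale raw non-negative counts to integer RSV in [0, 100].

    Each value maps to ``round_half_up(100 * v / max(raw))``.  An all-zero
    series stays all zero and is flagged ``degenerate``.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.size == 0:
        raise ValidationError("empty series")
    if np.any(arr < 0):
        raise ValidationError("raw counts must be non-negative")
    if dates is None:
        dates = [STUDY_START + dt.timedelta(days=i) for i in range(arr.size)]
    peak = arr.max()
    if peak == 0:
        vals = tuple(0 for _ in range(arr.size))
        return RsvSeries(keyword, geo, tuple(dates), vals, normalized=True, degenerate=True)
    vals = tuple(int(round_half_up(100.0 * v / peak)) for v in arr)
    return RsvSeries(keyword, geo, tuple(dates), vals, normalized=True)


def extract_peaks(series: RsvSeries, window_days: int = 7) -> list[PeakObservation]:
    """Tile the date range into consecutive ``window_days`` windows and take
    the maximum value in each non-empty window.

    Windows are anchored at the first observation date; a trailing partial
    window is kept, so the tiling is deterministic for any date range.
    """
    if window_days < 1:
        raise ValidationError("window_days must be >= 1")
    start = series.dates[0]
    peaks: dict[int, float] = {}
    for d, v in zip(series.dates, series.values):
        w = (d - start).days // window_days
        if w not in peaks or v > peaks[w]:
            peaks[w] = v
    return [PeakObservation(series.geo, w, peaks[w]) for w in sorted(peaks)]


def compute_apc(
    peaks: Sequence[PeakObservation],
    keyword: str = "",
    level: float = 0.95,
) -> ApcEstimate:
    """Average peak volume across geographies, with a Gaussian CI.

    Per geography *g* with ``n_g`` window peaks, let ``m_g`` be the mean and
    ``s_g^2`` the unbiased sample variance (0 when ``n_g == 1``).  Then

    * ``total = sum_g m_g``,
    * half-width ``= z_{(1+level)/2} * sqrt(sum_g s_g^2 / n_g)``,
    * CI ``= total -/+ half-width``, lower bound floored at 0.

    With a single observation per geography the CI collapses to the total.
    """
    if not peaks:
        raise ValidationError("empty peak set")
    if not 0 < level < 1:
        raise ValidationError("confidence level must lie in (0, 1)")
    by_geo: dict[str, list[float]] = {}
    for p in peaks:
        by_geo.setdefault(p.geo, []).append(float(p.peak_value))
    total = 0.0
    var_sum = 0.0
    for vals in by_geo.values():
        a = np.asarray(vals)
        total += float(a.mean())
        if a.size > 1:
            var_sum += float(a.var(ddof=1)) / a.size
    z = float(stats.norm.ppf((1 + level) / 2))
    hw = z * np.sqrt(var_sum)
    return ApcEstimate(
        keyword=keyword,
        total=total,
        ci_low=max(0.0, total - hw),
        ci_high=total + hw,
        n_obs=len(peaks),
        level=level,
        var_sum=var_sum,
    )


def detect_breakout(series: RsvSeries) -> list[dt.date]:
    """Dates at which the keyword reached breakout level (RSV = 100)."""
    if not series.normalized:
        raise ValidationError("breakout detection requires a normalized series")
    return [d for d, v in zip(series.dates, series.values) if v == 100]


def detect_spikes(series: RsvSeries, threshold: int = 50) -> list[tuple[dt.date, int]]:
    """Strict local maxima with value >= ``threshold``.

    An interior point spikes when strictly greater than both neighbours;
    an endpoint when strictly greater than its single neighbour.  A
    one-point series is its own maximum.  Flat stretches never spike.
    """
    if not 0 < threshold <= 100:
        raise ValidationError("threshold must lie in (0, 100]")
    v = series.values
    n = len(v)
    out = []
    for i in range(n):
        left_ok = i == 0 or v[i] > v[i - 1]
        right_ok = i == n - 1 or v[i] > v[i + 1]
        if left_ok and right_ok and v[i] >= threshold:
            out.append((series.dates[i], v[i]))
    return out


@dataclass(frozen=True)
class EventAlignment:
    """Spikes matched to nearest events within a day tolerance."""

    matches: tuple[tuple[tuple[dt.date, int], Event, int], ...]  # (spike, event, offset days)
    unmatched_spikes: tuple[tuple[dt.date, int], ...]
    unmatched_events: tuple[Event, ...]


def align_events(
    spikes: Sequence[tuple[dt.date, int]],
    events: Sequence[Event],
    tolerance_days: int = 2,
) -> EventAlignment:
    """Match each spike to the nearest event within ``tolerance_days``.

    Ties in distance are broken toward the earlier event.  Spikes without a
    close event, and events never matched, are reported separately.
    """
    if tolerance_days < 0:
        raise ValidationError("tolerance_days must be >= 0")
    evs = sorted(events, key=lambda e: e.date)
    matches = []
    unmatched_spikes = []
    used: set[int] = set()
    for spike in spikes:
        sd = spike[0]
        best: tuple[int, int] | None = None  # (abs offset, event index)
        for i, e in enumerate(evs):
            off = abs((e.date - sd).days)
            if off <= tolerance_days and (best is None or off < best[0]):
                best = (off, i)  # evs sorted by date -> first at min distance is earliest
        if best is None:
            unmatched_spikes.append(spike)
        else:
            used.add(best[1])
            matches.append((spike, evs[best[1]], (evs[best[1]].date - sd).days))
    unmatched_events = tuple(e for i, e in enumerate(evs) if i not in used)
    return EventAlignment(tuple(matches), tuple(unmatched_spikes), unmatched_events)


def rank_by_apc(estimates: Sequence[ApcEstimate], n: int = 10) -> list[ApcEstimate]:
    """Top ``n`` estimates by descending total; ties broken by ascending
    lexicographic keyword."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    return sorted(estimates, key=lambda e: (-e.total, e.keyword))[:n]


@dataclass(frozen=True)
class SeverityClassSummary:
    """Pooled APC for one severity class."""

    severity: str
    total_apc: float
    share: float
    share_excl_not_infodemic: float | None
    ci_low: float
    ci_high: float
    ci_method: str
    monikers: tuple[str, ...]


@dataclass(frozen=True)
class SeveritySummary:
    """APC totals pooled by I-scale severity class.

    ``share`` uses the grand total over all keywords; because published
    summaries are ambiguous about whether the not-infodemic class belongs in
    the denominator, ``share_excl_not_infodemic`` is also reported for the
    four infodemic classes.
    """

    classes: dict[str, SeverityClassSummary] = field(default_factory=dict)
    grand_total: float = 0.0
    level: float = 0.95


def aggregate_by_severity(
    estimates: Sequence[ApcEstimate],
    scores: Sequence[IScaleResult],
    level: float = 0.95,
    ci_method: str = "auto",
) -> SeveritySummary:
    """Pool APC totals by the severity class of each keyword.

    ``ci_method`` selects how class CIs are formed: ``"variance"`` propagates
    the members' variance terms (requires ``var_sum`` on every member),
    ``"bounds"`` sums the members' printed CI bounds, and ``"auto"`` uses
    variance propagation when every member carries a variance term and
    falls back to bounds otherwise.  Each class is tagged with the method
    actually used.
    """
    if ci_method not in ("auto", "variance", "bounds"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    by_kw = {}
    for s in scores:
        if s.moniker in by_kw:
            raise ValidationError(f"duplicate score for {s.moniker!r}")
        by_kw[s.moniker] = s
    missing = [e.keyword for e in estimates if e.keyword not in by_kw]
    if missing:
        raise ValidationError(f"keywords without I-scale score: {missing}")

    members: dict[str, list[ApcEstimate]] = {sev: [] for sev in SEVERITIES}
    for e in estimates:
        members[by_kw[e.keyword].severity].append(e)
    grand = sum(e.total for e in estimates)
    nonzero_denom = grand - sum(e.total for e in members["not_infodemic"])
    z = float(stats.norm.ppf((1 + level) / 2))

    classes = {}
    for sev in SEVERITIES:
        mem = members[sev]
        total = sum(e.total for e in mem)
        have_var = mem and all(e.var_sum is not None for e in mem)
        method = ci_method if ci_method != "auto" else ("variance" if have_var else "bounds")
        if method == "variance":
            if not have_var:
                raise ValidationError(f"class {sev!r}: variance terms unavailable")
            hw = z * np.sqrt(sum(e.var_sum for e in mem))
            lo, hi = max(0.0, total - hw), total + hw
        else:
            lo = sum(e.ci_low for e in mem)
            hi = sum(e.ci_high for e in mem)
        share = total / grand if grand > 0 else 0.0
        if sev == "not_infodemic" or nonzero_denom <= 0:
            share_ex = None
        else:
            share_ex = total / nonzero_denom
        classes[sev] = SeverityClassSummary(
            severity=sev,
            total_apc=total,
            share=share,
            share_excl_not_infodemic=share_ex,
            ci_low=lo,
            ci_high=hi,
            ci_method=method if mem else "empty",
            monikers=tuple(e.keyword for e in mem),
        )
    return SeveritySummary(classes=classes, grand_total=grand, level=level)


# ---------------------------------------------------------------------------
# CSV interfaces

def read_series_csv(path: str | Path, normalized: bool = True) -> list[RsvSeries]:
    """Read `keyword,geo,date,value` rows into one series per keyword x geo."""
    df = pd.read_csv(path, dtype={"keyword": str, "geo": str}, comment="#")
    need = {"keyword", "geo", "date", "value"}
    if not need.issubset(df.columns):
        raise ValidationError(f"series CSV must have columns {sorted(need)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    out = []
    for (kw, geo), g in df.groupby(["keyword", "geo"], sort=True):
        g = g.sort_values("date")
        vals = tuple(int(v) for v in g["value"])
        out.append(
            RsvSeries(
                keyword=kw,
                geo=geo,
                dates=tuple(g["date"]),
                values=vals,
                normalized=normalized,
                degenerate=all(v == 0 for v in vals),
            )
        )
    return out


def read_events_csv(path: str | Path) -> list[Event]:
    """Read `date,label,keyword` rows."""
    df = pd.read_csv(path, dtype={"label": str, "keyword": str}, comment="#")
    if not {"date", "label"}.issubset(df.columns):
        raise ValidationError("events CSV must have columns date,label[,keyword]")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    kw = df["keyword"] if "keyword" in df.columns else [""] * len(df)
    return [Event(d, str(l), "" if pd.isna(k) else str(k)) for d, l, k in zip(df["date"], df["label"], kw)]


def estimates_to_frame(estimates: Iterable[ApcEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.keyword, e.total, e.ci_low, e.ci_high, e.n_obs) for e in estimates],
        columns=["keyword", "total", "ci_low", "ci_high", "n_obs"],
    )


def plot_series(
    series: Sequence[RsvSeries],
    events: Sequence[Event] = (),
    path: str | Path | None = None,
):
    """Basic RSV time-series plot with event markers (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    for s in series:
        ax.plot(s.dates, s.values, label=f"{s.keyword} ({s.geo})")
    for e in events:
        ax.axvline(e.date, color="grey", ls="--", lw=0.8)
        ax.annotate(e.label, (e.date, 95), rotation=90, fontsize=7, va="top")
    ax.set_ylabel("relative search volume")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=8)
    fig.autofmt_xdate()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
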