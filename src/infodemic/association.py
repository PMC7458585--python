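"""Country-level association between search interest and disease incidence.

The question: do countries with more COVID-19 cases per million people
search more for the disease?  The measure is the Pearson product-moment
correlation over a country panel, with the usual two-sided Student-t test,

    r = sum (x - xbar)(y - ybar) / sqrt(sum (x - xbar)^2 sum (y - ybar)^2)
    t = r sqrt((n - 2) / (1 - r^2)),   t ~ t_{n-2} under rho = 0.

``r`` and ``t`` are computed directly from these formulas; only the
Student-t tail probability comes from scipy.  The interest measure entering
the panel is explicit and configurable (window-mean RSV by default, or the
APC total), since published correlations rarely state which one was used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .trends import RsvSeries, compute_apc, extract_peaks

__all__ = [
    "CountryObservation",
    "CorrelationResult",
    "pearson",
    "build_panel",
    "format_p",
]


@dataclass(frozen=True)
class CountryObservation:
    """One country's search interest and incidence (cases per 1M people)."""

    country: str
    interest: float
    incidence: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    p_value: float


def format_p(p: float, floor: float = 0.001) -> str:
    """Display convention: p-values below ``floor`` print as '<.001'."""
    if p < floor:
        return f"<{str(floor).lstrip('0')}"
    return f"{p:.3f}".lstrip("0")


def pearson(panel: Sequence[CountryObservation]) -> CorrelationResult:
    """Pearson correlation of interest vs incidence with a two-sided test."""
    n = len(panel)
    if n < 3:
        raise ValidationError(f"need at least 3 observations, got {n}")
    x = np.asarray([o.interest for o in panel], dtype=float)
    y = np.asarray([o.incidence for o in panel], dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise ValidationError("zero variance in one of the variables")
    r = float(dx @ dy) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(r=r, n=n, t_stat=float(t), p_value=min(1.0, p))


def build_panel(
    series: Sequence[RsvSeries],
    incidence: Mapping[str, float] | pd.DataFrame,
    measure: str = "mean_rsv",
    window_days: int = 7,
) -> list[CountryObservation]:
    """Inner-join per-country search series with an incidence table.

    ``series`` carries one RSV series per country (the ``geo`` field names
    the country).  ``incidence`` maps country to cases per 1M people, or is
    a DataFrame with ``country`` and ``incidence`` columns.  ``measure``
    selects the interest summary: ``"mean_rsv"`` (window-mean RSV, default)
    or ``"apc"`` (the APC total of that country's series alone).
    """
    if measure not in ("mean_rsv", "apc"):
        raise ValidationError(f"unknown interest measure {measure!r}")
    if isinstance(incidence, pd.DataFrame):
        if not {"country", "incidence"}.issubset(incidence.columns):
            raise ValidationError("incidence table needs columns country,incidence")
        dup = incidence["country"][incidence["country"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate country rows in incidence: {sorted(set(dup))}")
        inc_map = dict(zip(incidence["country"], incidence["incidence"]))
    else:
        inc_map = dict(incidence)

    by_country: dict[str, RsvSeries] = {}
    for s in series:
        if s.geo in by_country:
            raise ValidationError(f"duplicate series for country {s.geo!r}")
        by_country[s.geo] = s

    common = [c for c in by_country if c in inc_map]
    if not common:
        raise ValidationError("no countries common to the series and incidence table")
    panel = []
    for c in common:
        s = by_country[c]
        if measure == "mean_rsv":
            interest = float(np.mean(s.values))
        else:
            interest = compute_apc(extract_peaks(s, window_days), keyword=s.keyword).total
        panel.append(CountryObservation(country=c, interest=interest, incidence=float(inc_map[c])))
    return panel
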