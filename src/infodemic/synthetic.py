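"""Synthetic inputs with known ground truth.

Real Google Trends extracts and Instagram tag counts are proprietary
snapshots that cannot be redistributed, so every pipeline input can be
generated here with its ground truth attached:

* :func:`gen_raw_series` — raw daily search counts per geography: a constant
  baseline plus triangular spike kernels at chosen days plus Gaussian noise,
  floored at 0.  The triangular kernel makes the argmax analytic, so spike-
  and breakout-detection tests can be exact;
* :func:`gen_hashtag_table` — a single multinomial draw over a tag
  probability simplex;
* :func:`gen_country_panel` — a bivariate lognormal country panel whose
  latent Gaussian correlation is ``rho``; the correlation of the observable
  (exponentiated) pair is smaller, and the generator reports it exactly via
  the lognormal closed form ``(e^rho - 1)/(e - 1)`` so recovery tests have
  an honest target;
* :func:`gen_annotations` — random (or exhaustively enumerated) valid
  rubric annotations.

Every generator is a pure function of its scenario and seed.
"""

from __future__ import annotations

import datetime as dt
import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .association import CountryObservation
from .errors import ValidationError
from .hashtags import GROUPS, HashtagCount
from .iscale import CategoryPoints, MonikerAnnotation
from .trends import STUDY_START

__all__ = [
    "SeriesScenario",
    "PanelScenario",
    "SyntheticSeries",
    "gen_raw_series",
    "gen_hashtag_table",
    "gen_country_panel",
    "gen_annotations",
    "realized_rho",
    "latent_rho_for",
    "DEFAULT_SEED",
]

#: Default seed encodes the study start date (2020-02-20).
DEFAULT_SEED = 20200220


@dataclass(frozen=True)
class SeriesScenario:
    """Recipe for spiky raw search-count series.

    Defaults mirror the study window: 77 daily observations starting
    2020-02-20 (through 2020-05-06), a low search baseline with mild noise,
    and two event-driven spikes (a mid-window story and a late, dominant
    one) of the kind seen in real breakout queries.
    """

    n_days: int = 77
    baseline: float = 10.0
    noise_sd: float = 3.0
    spikes: tuple[tuple[int, float], ...] = ((34, 40.0), (57, 90.0))
    geos: tuple[str, ...] = ("GLOBAL",)
    seed: int = DEFAULT_SEED
    spike_width: int = 5
    start: dt.date = STUDY_START

    def __post_init__(self):
        if self.n_days < 1:
            raise ValidationError("n_days must be >= 1")
        if self.baseline < 0 or self.noise_sd < 0:
            raise ValidationError("baseline and noise_sd must be >= 0")
        if self.spike_width < 1:
            raise ValidationError("spike_width must be >= 1")
        for day, mag in self.spikes:
            if not 0 <= day < self.n_days:
                raise ValidationError(f"spike day {day} outside [0, {self.n_days})")
            if mag <= 0:
                raise ValidationError("spike magnitudes must be > 0")


@dataclass(frozen=True)
class SyntheticSeries:
    """Raw counts per geography plus the injected ground truth."""

    dates: tuple[dt.date, ...]
    raw: dict[str, np.ndarray]
    true_spikes: tuple[tuple[int, float], ...]


def gen_raw_series(scenario: SeriesScenario) -> SyntheticSeries:
    """Raw daily counts: baseline + triangular spike kernels + noise, >= 0.

    The kernel at ``(day, mag)`` contributes ``mag * (1 - |t - day|/width)``
    for ``|t - day| < width``, peaking exactly at ``day``.  Noise is i.i.d.
    Gaussian per day and geography; output is deterministic given the seed.
    """
    rng = np.random.default_rng(scenario.seed)
    t = np.arange(scenario.n_days)
    signal = np.full(scenario.n_days, scenario.baseline, dtype=float)
    for day, mag in scenario.spikes:
        signal += mag * np.clip(1.0 - np.abs(t - day) / scenario.spike_width, 0.0, None)
    raw = {}
    for geo in scenario.geos:
        noise = rng.normal(0.0, scenario.noise_sd, scenario.n_days) if scenario.noise_sd > 0 else 0.0
        raw[geo] = np.maximum(0.0, signal + noise)
    dates = tuple(scenario.start + dt.timedelta(days=int(i)) for i in t)
    return SyntheticSeries(dates=dates, raw=raw, true_spikes=tuple(scenario.spikes))


def gen_hashtag_table(
    probs: Sequence[float],
    total: int,
    seed: int = DEFAULT_SEED,
    tags: Sequence[str] | None = None,
    groups: Sequence[str] | None = None,
) -> list[HashtagCount]:
    """One multinomial draw of ``total`` posts over the tag simplex."""
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size == 0 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("probs must be a probability simplex (sum 1 within 1e-9)")
    if total <= 0:
        raise ValidationError("total must be > 0")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(total, p / p.sum())
    if tags is None:
        tags = [f"#tag{i:02d}" for i in range(p.size)]
    if groups is None:
        groups = [GROUPS[i % len(GROUPS)] for i in range(p.size)]
    if len(tags) != p.size or len(groups) != p.size:
        raise ValidationError("tags/groups length must match probs")
    return [HashtagCount(t, int(c), g) for t, c, g in zip(tags, counts, groups)]


def realized_rho(rho: float) -> float:
    """Pearson correlation of (e^Z1, e^Z2) when corr(Z1, Z2) = rho.

    For unit-variance bivariate normals the lognormal pair has correlation
    (e^rho - 1)/(e - 1); the exponential map shrinks |rho|, so recovery
    tests target this value, not the latent one.
    """
    if not -1.0 < rho < 1.0:
        raise ValidationError("rho must lie in (-1, 1)")
    return float(np.expm1(rho) / np.expm1(1.0))


def latent_rho_for(target: float) -> float:
    """Inverse of :func:`realized_rho`: latent Gaussian correlation giving a
    desired observable correlation."""
    if not -1.0 < target < 1.0:
        raise ValidationError("target must lie in (-1, 1)")
    rho = float(np.log1p(target * np.expm1(1.0)))
    if not -1.0 < rho < 1.0:
        raise ValidationError(f"target {target} not reachable by a latent rho in (-1, 1)")
    return rho


@dataclass(frozen=True)
class PanelScenario:
    """Recipe for a correlated country panel.

    The default latent correlation is chosen so the observable pair has a
    Pearson correlation of 0.45, the magnitude seen between national search
    interest and COVID-19 incidence in spring 2020; 40 countries is a
    realistic panel size for such cross-national snapshots.

    ``transform`` selects the map from the latent Gaussian pair to positive
    observables: ``"exp"`` (default) exponentiates, giving right-skewed
    lognormal panels like real incidence data — this shrinks the observable
    correlation to :func:`realized_rho` and fattens the sampling tails of
    the Pearson estimate; ``"normal"`` applies an affine shift instead,
    preserving the correlation exactly and the normal-theory sampling error
    (1 - rho^2)/sqrt(n) — the right choice when a test's tolerance is
    derived from Gaussian sampling theory.
    """

    n_countries: int = 40
    rho: float = field(default_factory=lambda: latent_rho_for(0.45))
    interest_scale: float = 50.0
    incidence_scale: float = 1000.0
    seed: int = DEFAULT_SEED
    transform: str = "exp"

    def __post_init__(self):
        if self.n_countries < 3:
            raise ValidationError("n_countries must be >= 3")
        if not -1.0 < self.rho < 1.0:
            raise ValidationError("rho must lie in (-1, 1)")
        if self.interest_scale <= 0 or self.incidence_scale <= 0:
            raise ValidationError("scales must be > 0")
        if self.transform not in ("exp", "normal"):
            raise ValidationError("transform must be 'exp' or 'normal'")


def gen_country_panel(scenario: PanelScenario) -> tuple[list[CountryObservation], float]:
    """Correlated bivariate-lognormal country panel.

    Draws standard bivariate normals with latent correlation ``rho`` via the
    Cholesky construction, then maps them to positive support per
    ``scenario.transform`` and scales linearly.  Returns the panel and the
    true observable correlation for recovery tests: :func:`realized_rho` of
    the latent one under ``"exp"``, the latent ``rho`` itself under
    ``"normal"`` (affine maps leave Pearson correlation unchanged).
    """
    rng = np.random.default_rng(scenario.seed)
    n, rho = scenario.n_countries, scenario.rho
    z = rng.standard_normal((n, 2))
    z2 = rho * z[:, 0] + np.sqrt(1.0 - rho * rho) * z[:, 1]
    if scenario.transform == "exp":
        a, b = np.exp(z[:, 0]), np.exp(z2)
        truth = realized_rho(rho)
    else:
        # shift 8 sd into the positive half-line: P(z < -8) ~ 6e-16
        a, b = z[:, 0] + 8.0, z2 + 8.0
        truth = rho
    interest = scenario.interest_scale * a
    incidence = scenario.incidence_scale * b
    panel = [
        CountryObservation(country=f"C{i:03d}", interest=float(x), incidence=float(y))
        for i, (x, y) in enumerate(zip(interest, incidence))
    ]
    return panel, truth


def gen_annotations(
    n: int,
    seed: int = DEFAULT_SEED,
    exhaustive: bool = False,
) -> list[MonikerAnnotation]:
    """Random valid rubric annotations with unique synthetic monikers.

    With ``exhaustive=True`` all 3^5 = 243 category-point combinations are
    enumerated exactly once (``n`` is ignored) — useful for oracle tests.
    """
    if exhaustive:
        combos = list(itertools.product((0, 1, 2), repeat=5))
    else:
        if n < 0:
            raise ValidationError("n must be >= 0")
        rng = np.random.default_rng(seed)
        combos = [tuple(int(v) for v in rng.integers(0, 3, size=5)) for _ in range(n)]
    return [
        MonikerAnnotation(
            moniker=f"moniker-{i:04d}",
            points=CategoryPoints(*combo),
        )
        for i, combo in enumerate(combos)
    ]
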