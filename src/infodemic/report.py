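"""End-to-end pipeline: score, summarise, and write one JSON report.

``run_pipeline`` wires the stages together — rubric scoring, APC estimation
(or loading printed APC tables), severity aggregation, hashtag shares, and
the country-level correlation — and returns a report dictionary with stable
field ordering.  Any input path left unset falls back to the bundled
example tables (and, for the country panel, to the synthetic generator), so
the default run reproduces the study-window headline numbers end to end.

Serialization rules: display floats are rounded half-up (shares to 1
decimal, correlation r to 2 decimals); full-precision values live under
the ``raw`` key.  Identical config + seed gives byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import datasets
from ._rounding import round_half_up
from .association import build_panel, format_p, pearson
from .errors import InfodemicError, StageError, ValidationError
from .hashtags import combined_share, group_summary, shares, shares_to_frame, read_hashtags_csv
from .iscale import read_annotations_csv, results_to_frame, score_table
from .synthetic import DEFAULT_SEED, PanelScenario, gen_country_panel
from .trends import (
    aggregate_by_severity,
    align_events,
    compute_apc,
    detect_breakout,
    detect_spikes,
    estimates_to_frame,
    extract_peaks,
    read_events_csv,
    read_series_csv,
)

log = logging.getLogger("infodemic")

__all__ = ["RunConfig", "run_pipeline", "write_report", "validate_report", "REPORT_SECTIONS"]

REPORT_SECTIONS = ("meta", "iscale", "apc", "severity", "hashtags", "association", "raw")


@dataclass
class RunConfig:
    """Inputs and tuning parameters for one pipeline run.

    Unset paths fall back to the bundled tables; ``panel_path`` falls back
    to a synthetic panel drawn with ``seed``.
    """

    annotations_path: str | None = None
    series_path: str | None = None
    events_path: str | None = None
    hashtags_path: str | None = None
    panel_path: str | None = None
    window_days: int = 7
    confidence_level: float = 0.95
    spike_threshold: int = 50
    tolerance_days: int = 2
    share_method: str = "sum_of_rounded"
    combined_tags: tuple[str, ...] = ("#COVID19", "#coronavirus")
    seed: int = DEFAULT_SEED
    out_dir: str | None = None

    def validate(self) -> "RunConfig":
        if self.window_days < 1:
            raise ValidationError("window_days must be >= 1")
        if not 0 < self.confidence_level < 1:
            raise ValidationError("confidence_level must lie in (0, 1)")
        if not 0 < self.spike_threshold <= 100:
            raise ValidationError("spike_threshold must lie in (0, 100]")
        if self.tolerance_days < 0:
            raise ValidationError("tolerance_days must be >= 0")
        if self.share_method not in ("sum_of_rounded", "exact"):
            raise ValidationError(f"unknown share_method {self.share_method!r}")
        for name in ("annotations_path", "series_path", "events_path", "hashtags_path", "panel_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{name} does not exist: {p}")
        return self


def _stage(name):
    """Decorator tagging failures with the stage that produced them."""

    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except (InfodemicError, OSError, pd.errors.ParserError, KeyError) as exc:
                raise StageError(name, str(exc)) from exc

        return wrapped

    return deco


@_stage("iscale")
def _run_iscale(cfg: RunConfig):
    if cfg.annotations_path:
        annotations = read_annotations_csv(cfg.annotations_path)
    else:
        annotations = datasets.load_keyword_annotations()
    if not annotations:
        raise ValidationError("no annotations to score")
    results = score_table(annotations)
    log.info("iscale: scored %d monikers", len(results))
    return results


@_stage("trends")
def _run_trends(cfg: RunConfig):
    """APC estimates plus per-keyword spike/breakout diagnostics."""
    if cfg.series_path:
        series = read_series_csv(cfg.series_path)
        events = read_events_csv(cfg.events_path) if cfg.events_path else []
        by_kw: dict[str, list] = {}
        for s in series:
            by_kw.setdefault(s.keyword, []).append(s)
        estimates, diagnostics = [], {}
        for kw in sorted(by_kw):
            peaks = []
            breakouts, spikes, matches = [], [], []
            for s in by_kw[kw]:
                peaks.extend(extract_peaks(s, cfg.window_days))
                breakouts.extend(detect_breakout(s))
                spikes.extend(detect_spikes(s, cfg.spike_threshold))
            estimates.append(compute_apc(peaks, keyword=kw, level=cfg.confidence_level))
            kw_events = [e for e in events if not e.keyword or e.keyword == kw]
            alignment = align_events(spikes, kw_events, cfg.tolerance_days)
            diagnostics[kw] = {
                "breakouts": [d.isoformat() for d in sorted(breakouts)],
                "spikes": [[d.isoformat(), int(v)] for d, v in sorted(spikes)],
                "matched_events": [
                    {"spike_date": sp[0].isoformat(), "event": ev.label, "offset_days": off}
                    for sp, ev, off in alignment.matches
                ],
            }
        log.info("trends: %d keywords, %d series", len(estimates), len(series))
        return estimates, diagnostics
    estimates, _ = datasets.load_keyword_apc("all")
    log.info("trends: loaded %d bundled keyword APC rows", len(estimates))
    return estimates, {}


@_stage("severity")
def _run_severity(cfg: RunConfig, estimates, scores):
    return aggregate_by_severity(estimates, scores, level=cfg.confidence_level)


@_stage("hashtags")
def _run_hashtags(cfg: RunConfig):
    counts = read_hashtags_csv(cfg.hashtags_path) if cfg.hashtags_path else datasets.load_hashtag_counts()
    table = shares(counts)
    combined = combined_share(counts, cfg.combined_tags, method=cfg.share_method)
    groups = group_summary(counts)
    log.info("hashtags: %d tags, grand total %d", len(table.rows), table.grand_total)
    return table, combined, groups


@_stage("association")
def _run_association(cfg: RunConfig):
    if cfg.panel_path:
        df = pd.read_csv(cfg.panel_path, comment="#")
        if not {"country", "interest", "incidence"}.issubset(df.columns):
            raise ValidationError("panel CSV needs columns country,interest,incidence")
        from .association import CountryObservation

        panel = [
            CountryObservation(str(r.country), float(r.interest), float(r.incidence))
            for r in df.itertuples(index=False)
        ]
        true_rho = None
    else:
        panel, true_rho = gen_country_panel(PanelScenario(seed=cfg.seed))
    res = pearson(panel)
    log.info("association: n=%d, r=%.3f", res.n, res.r)
    return res, true_rho


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and assemble the report dictionary.

    Raises :class:`StageError` naming the failing stage; when ``out_dir``
    is set, per-stage CSV/JSON artifacts and ``report.json`` are written
    there only after every stage has succeeded (no partial outputs).
    """
    cfg = config.validate()
    scores = _run_iscale(cfg)
    estimates, diagnostics = _run_trends(cfg)
    severity = _run_severity(cfg, estimates, scores)
    table, combined, groups = _run_hashtags(cfg)
    corr, true_rho = _run_association(cfg)

    report = {
        "meta": {
            "package": "infodemic",
            "seed": cfg.seed,
            "window_days": cfg.window_days,
            "confidence_level": cfg.confidence_level,
            "spike_threshold": cfg.spike_threshold,
            "tolerance_days": cfg.tolerance_days,
            "share_method": cfg.share_method,
        },
        "iscale": {
            "n_monikers": len(scores),
            "scores": [
                {"moniker": r.moniker, "score": r.score, "severity": r.severity} for r in scores
            ],
        },
        "apc": {
            "estimates": [
                {
                    "keyword": e.keyword,
                    "total": e.total,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "n_obs": e.n_obs,
                }
                for e in estimates
            ],
            "diagnostics": diagnostics,
        },
        "severity": {
            "grand_total": severity.grand_total,
            "classes": {
                sev: {
                    "total_apc": c.total_apc,
                    "share_pct": round_half_up(100 * c.share, 1),
                    "share_excl_not_infodemic_pct": (
                        None
                        if c.share_excl_not_infodemic is None
                        else round_half_up(100 * c.share_excl_not_infodemic, 1)
                    ),
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                    "ci_method": c.ci_method,
                    "monikers": list(c.monikers),
                }
                for sev, c in severity.classes.items()
            },
        },
        "hashtags": {
            "grand_total": table.grand_total,
            "shares": [
                {"tag": r.tag, "count": r.count, "share_pct": r.display_share} for r in table.rows
            ],
            "combined": {
                "tags": list(cfg.combined_tags),
                "share_pct": combined.percent,
                "count": combined.count,
                "method": combined.method,
            },
            "groups": {
                g: {"total": int(v["total"]), "share_pct": round_half_up(100 * v["share"], 1)}
                for g, v in sorted(groups.items())
            },
        },
        "association": {
            "r": round_half_up(corr.r, 2),
            "n": corr.n,
            "p_display": format_p(corr.p_value),
            "true_rho": None if true_rho is None else round_half_up(true_rho, 2),
        },
        "raw": {
            "severity_shares": {sev: c.share for sev, c in severity.classes.items()},
            "hashtag_exact_shares": {r.tag: r.exact_share for r in table.rows},
            "correlation": {"r": corr.r, "t_stat": corr.t_stat, "p_value": corr.p_value},
        },
    }

    if cfg.out_dir:
        _write_artifacts(cfg, report, scores, estimates, table)
    return report


def _write_artifacts(cfg: RunConfig, report, scores, estimates, table):
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        for name, writer in [
            ("scored_monikers.csv", lambda p: results_to_frame(scores).to_csv(p, index=False)),
            ("apc.csv", lambda p: estimates_to_frame(estimates).to_csv(p, index=False)),
            ("hashtag_shares.csv", lambda p: shares_to_frame(table).to_csv(p, index=False)),
            ("report.json", lambda p: write_report(report, p)),
        ]:
            path = out / name
            writer(path)
            written.append(path)
    except Exception:
        for p in written:  # no partial output bundles
            p.unlink(missing_ok=True)
        raise


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a validated report with stable ordering."""
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")


def validate_report(report: dict) -> dict:
    """Check the report carries every required section."""
    missing = [s for s in REPORT_SECTIONS if s not in report]
    if missing:
        raise ValidationError(f"report missing sections: {missing}")
    return report
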