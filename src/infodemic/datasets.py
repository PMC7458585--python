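"""Bundled example tables.

Small reference tables from the February 20 - May 6, 2020 global COVID-19
search window ship with the package so the full pipeline can run, and its
summary statistics be reproduced, without any external data:

* keyword APC tables (global scientific/infodemic keywords and fake-news
  keywords) with printed 95% CIs and I-scale scores;
* per-category rubric annotations for those keywords — these are SYNTHETIC
  reconstructions consistent with the rubric rules, since only total scores
  were published;
* Instagram hashtag post counts for the virus-name tags;
* country-level hashtag counts (displayed as multiples of 100,000);
* the news-event log used for spike alignment.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .hashtags import HashtagCount, read_hashtags_csv
from .iscale import IScaleResult, MonikerAnnotation, classify_severity, read_annotations_csv
from .trends import ApcEstimate, Event, read_events_csv

__all__ = [
    "data_path",
    "load_keyword_apc",
    "load_keyword_annotations",
    "load_hashtag_counts",
    "load_country_hashtags",
    "load_events",
]


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    p = resources.files("infodemic.data") / name
    with resources.as_file(p) as fp:
        if not fp.exists():
            raise ValidationError(f"no bundled data file {name!r}")
        return Path(fp)


def load_keyword_apc(table: str = "global") -> tuple[list[ApcEstimate], list[IScaleResult]]:
    """Keyword APC estimates and I-scale results from a bundled table.

    ``table`` is ``"global"``, ``"fakenews"`` or ``"all"`` (both
    concatenated).  The estimates carry the printed totals and CI bounds
    but no variance terms, so severity aggregation falls back to
    sum-of-bounds class CIs.
    """
    names = {
        "global": ["global_keywords_apc.csv"],
        "fakenews": ["fakenews_keywords_apc.csv"],
        "all": ["global_keywords_apc.csv", "fakenews_keywords_apc.csv"],
    }
    if table not in names:
        raise ValidationError(f"unknown table {table!r} (use global, fakenews or all)")
    estimates, scores = [], []
    for fname in names[table]:
        df = pd.read_csv(data_path(fname), comment="#")
        for row in df.itertuples(index=False):
            estimates.append(
                ApcEstimate(
                    keyword=str(row.moniker),
                    total=float(row.total_apc),
                    ci_low=float(row.ci_low),
                    ci_high=float(row.ci_high),
                    n_obs=1,
                )
            )
            score = int(row.iscale)
            scores.append(IScaleResult(str(row.moniker), score, classify_severity(score)))
    return estimates, scores


def load_keyword_annotations() -> list[MonikerAnnotation]:
    """Synthetic per-category rubric annotations for the bundled keywords."""
    return read_annotations_csv(data_path("keyword_annotations_synthetic.csv"))


def load_hashtag_counts() -> list[HashtagCount]:
    """Instagram post counts for the virus-name hashtag set."""
    return read_hashtags_csv(data_path("instagram_hashtags.csv"))


def load_country_hashtags() -> pd.DataFrame:
    """Country-level hashtag counts (columns ``country,hashtag_count``)."""
    return pd.read_csv(data_path("country_hashtags.csv"), comment="#")


def load_events() -> list[Event]:
    """News events aligned with search spikes in the study window."""
    return read_events_csv(data_path("events.csv"))
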