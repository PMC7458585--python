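"""Hashtag frequency shares and display scaling.

Post counts for a fixed set of hashtags are turned into shares of the set's
grand total.  Two conventions for combining shares of a subset coexist in
published summaries:

* ``sum_of_rounded`` — add the individually rounded display percentages
  (e.g. 35.6 + 30.5 = 66.1); this is the convention behind published
  combined figures and is the default;
* ``exact`` — round the exact combined ratio (the same counts give 66.2).

Both are implemented; the difference is pure rounding.  Counts are post
counts, not distinct users, and shares are always relative to the provided
table's grand total, never to a platform-wide total.  Country-level counts
are displayed as multiples of 100,000 (:func:`to_multiples`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._rounding import round_half_up
from .errors import ValidationError

__all__ = [
    "GROUPS",
    "HashtagCount",
    "ShareRow",
    "ShareTable",
    "CombinedShare",
    "normalize_tag",
    "shares",
    "combined_share",
    "to_multiples",
    "group_summary",
    "read_hashtags_csv",
    "shares_to_frame",
]

GROUPS = ("scientific", "infodemic", "health", "other")


def normalize_tag(tag: str) -> str:
    """Canonical tag key: trimmed, leading '#' stripped, case-folded."""
    return tag.strip().lstrip("#").casefold()


@dataclass(frozen=True)
class HashtagCount:
    """One hashtag with its post count and thematic group."""

    tag: str
    count: int
    group: str = "other"

    def __post_init__(self):
        if self.count < 0:
            raise ValidationError(f"negative count for {self.tag!r}")
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r} (use one of {GROUPS})")


@dataclass(frozen=True)
class ShareRow:
    tag: str
    count: int
    exact_share: float  # fraction of the grand total
    display_share: float  # percent, half-up rounded to 1 decimal


@dataclass(frozen=True)
class ShareTable:
    rows: tuple[ShareRow, ...]
    grand_total: int

    def row(self, tag: str) -> ShareRow:
        key = normalize_tag(tag)
        for r in self.rows:
            if normalize_tag(r.tag) == key:
                return r
        raise ValidationError(f"unknown tag {tag!r}")


def _check_unique(table: Sequence[HashtagCount]) -> None:
    seen: set[str] = set()
    for h in table:
        k = normalize_tag(h.tag)
        if k in seen:
            raise ValidationError(f"duplicate tag after normalization: {h.tag!r}")
        seen.add(k)


def shares(table: Sequence[HashtagCount]) -> ShareTable:
    """Exact and display (1-decimal percent) shares of each tag."""
    _check_unique(table)
    grand = sum(h.count for h in table)
    if grand <= 0:
        raise ValidationError("all counts are zero; shares undefined")
    rows = tuple(
        ShareRow(
            tag=h.tag,
            count=h.count,
            exact_share=h.count / grand,
            display_share=round_half_up(100.0 * h.count / grand, 1),
        )
        for h in table
    )
    return ShareTable(rows=rows, grand_total=grand)


@dataclass(frozen=True)
class CombinedShare:
    percent: float
    count: int
    method: str


def combined_share(
    table: Sequence[HashtagCount],
    subset: Iterable[str],
    method: str = "sum_of_rounded",
) -> CombinedShare:
    """Combined percentage share of a subset of tags.

    ``sum_of_rounded`` adds the members' display shares (the convention used
    in published combined figures); ``exact`` rounds the combined ratio.
    """
    if method not in ("sum_of_rounded", "exact"):
        raise ValidationError(f"unknown method {method!r}")
    st = shares(table)
    keys = [normalize_tag(t) for t in subset]
    rows = [st.row(k) for k in keys]  # raises on unknown tag
    count = sum(r.count for r in rows)
    if method == "sum_of_rounded":
        pct = round_half_up(sum(r.display_share for r in rows), 1)
    else:
        pct = round_half_up(100.0 * count / st.grand_total, 1)
    return CombinedShare(percent=pct, count=count, method=method)


def to_multiples(count: int, base: int = 100_000) -> float:
    """Display scaling: a count expressed in multiples of ``base``, 2 dp."""
    if count < 0:
        raise ValidationError("count must be >= 0")
    if base <= 0:
        raise ValidationError("base must be > 0")
    return round_half_up(count / base, 2)


def group_summary(table: Sequence[HashtagCount]) -> dict[str, dict[str, float]]:
    """Total count and share per thematic group label."""
    _check_unique(table)
    grand = sum(h.count for h in table)
    if grand <= 0:
        raise ValidationError("all counts are zero; group shares undefined")
    out: dict[str, dict[str, float]] = {}
    for h in table:
        g = out.setdefault(h.group, {"total": 0, "share": 0.0})
        g["total"] += h.count
    for g in out.values():
        g["share"] = g["total"] / grand
    return out


# ---------------------------------------------------------------------------
# CSV interface: tag,count,group

def read_hashtags_csv(path: str | Path) -> list[HashtagCount]:
    # no comment handling: '#' legitimately starts tag values
    df = pd.read_csv(path, dtype={"tag": str, "group": str})
    if not {"tag", "count"}.issubset(df.columns):
        raise ValidationError("hashtags CSV must have columns tag,count[,group]")
    groups = df["group"] if "group" in df.columns else ["other"] * len(df)
    return [
        HashtagCount(str(t), int(c), str(g))
        for t, c, g in zip(df["tag"], df["count"], groups)
    ]


def shares_to_frame(table: ShareTable) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.tag, r.count, r.exact_share, r.display_share) for r in table.rows],
        columns=["tag", "count", "exact_share", "display_share"],
    )
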