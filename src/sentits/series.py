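"""Building the analysis rate series from coded comments.

Label sets are merged into the two analysis outcomes (support doctor /
blame doctor), comments are averaged per calendar date into daily rates,
and dates too sparse to carry a rate of their own (fewer than 2 comments)
are pooled with adjacent sparse dates into 3-4 day frames represented by
the frame's second date.  The retained points are indexed t = 0, 1, 2, ...
in order; the regression runs on this point index, not on calendar days.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .categories import (
    BLAME_GROUP,
    BLAME_TAG,
    CATEGORIES,
    OTHER_TAG,
    SUPPORT_GROUP,
    SUPPORT_TAG,
    validate_labels,
)
from .types import CodedComment, Comment, DatedLabels, SeriesPoint

logger = logging.getLogger(__name__)


def combine_categories(labels: Iterable[str]) -> frozenset:
    """Merge a nine-category label set into the analysis outcomes.

    Blame Doctor and Support Patient voice the same side and merge into
    ``blame_doctor``; Blame Patient and Support Doctor merge into
    ``support_doctor``.  A multi-label comment can carry both merged tags;
    a comment touched by neither merge is ``other``.
    """
    labels = validate_labels(labels)
    tags = set()
    if labels & SUPPORT_GROUP:
        tags.add(SUPPORT_TAG)
    if labels & BLAME_GROUP:
        tags.add(BLAME_TAG)
    if not tags:
        tags.add(OTHER_TAG)
    return frozenset(tags)


def attach_dates(
    comments: Sequence[Comment], codes: Sequence[CodedComment]
) -> list[DatedLabels]:
    """Join consensus codes with comment dates (inner join on comment_id)."""
    dates = {c.comment_id: c.date for c in comments}
    out = []
    for code in codes:
        if code.comment_id in dates:
            out.append(DatedLabels(code.comment_id, dates[code.comment_id], code.labels))
    return out


def daily_rates(coded: Sequence[DatedLabels]) -> pd.DataFrame:
    """Per-date merged sentiment rates.

    For each calendar date, ``support_rate`` is the share of that date's
    comments carrying the support-doctor tag (and likewise ``blame_rate``);
    the denominator is every comment on the date, including N/A and other.
    Returns a date-indexed frame with columns n, n_support, n_blame,
    support_rate, blame_rate.
    """
    rows = []
    for item in coded:
        tags = combine_categories(item.labels)
        rows.append(
            {
                "date": item.date,
                "support": SUPPORT_TAG in tags,
                "blame": BLAME_TAG in tags,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["n", "n_support", "n_blame", "support_rate", "blame_rate"]
        )
    df = pd.DataFrame(rows)
    g = df.groupby("date", sort=True).agg(
        n=("support", "size"), n_support=("support", "sum"), n_blame=("blame", "sum")
    )
    g["support_rate"] = g["n_support"] / g["n"]
    g["blame_rate"] = g["n_blame"] / g["n"]
    return g


def frame_sparse_dates(
    daily: pd.DataFrame, min_comments: int = 2, max_window: int = 4
) -> list[SeriesPoint]:
    """Turn daily rates into the analysis series, pooling sparse dates.

    Dates with at least ``min_comments`` comments become points directly.
    Runs of consecutive sparse dates are grouped greedily left-to-right into
    frames of 3 days (extended to 4 when exactly 4 remain, so no singleton
    is left); each frame is pooled into one point whose representative date
    is the frame's second date.  Leftover sparse dates shorter than a frame
    are merged into the preceding frame of the same run, or emitted as
    single points (logged) when the run never reached frame length.
    """
    if daily.empty:
        return []
    recs = [
        (date, int(row["n"]), int(row["n_support"]), int(row["n_blame"]))
        for date, row in daily.iterrows()
    ]
    points: list[dict] = []   # dicts: date, n, ns, nb, framed
    i, m = 0, len(recs)
    while i < m:
        date, n, ns, nb = recs[i]
        if n >= min_comments:
            points.append(dict(date=date, n=n, ns=ns, nb=nb, framed=False))
            i += 1
            continue
        run = []
        while i < m and recs[i][1] < min_comments:
            run.append(recs[i])
            i += 1
        j, run_frames = 0, []
        while len(run) - j >= 3:
            width = 4 if len(run) - j == 4 else 3
            chunk = run[j:j + width]
            run_frames.append(
                dict(
                    date=chunk[1][0],
                    n=sum(r[1] for r in chunk),
                    ns=sum(r[2] for r in chunk),
                    nb=sum(r[3] for r in chunk),
                    framed=True,
                )
            )
            j += width
        leftover = run[j:]
        if leftover and run_frames:
            tail = run_frames[-1]
            tail["n"] += sum(r[1] for r in leftover)
            tail["ns"] += sum(r[2] for r in leftover)
            tail["nb"] += sum(r[3] for r in leftover)
        elif leftover:
            logger.info(
                "emitting %d sparse date(s) as single points (run too short to frame)",
                len(leftover),
            )
            for r in leftover:
                run_frames.append(dict(date=r[0], n=r[1], ns=r[2], nb=r[3], framed=False))
        points.extend(run_frames)
    return [
        SeriesPoint(
            t=t,
            date=p["date"],
            support_rate=p["ns"] / p["n"],
            blame_rate=p["nb"] / p["n"],
            n_comments=p["n"],
            framed=p["framed"],
        )
        for t, p in enumerate(points)
    ]


def build_series(
    comments: Sequence[Comment],
    codes: Sequence[CodedComment],
    min_comments: int = 2,
) -> list[SeriesPoint]:
    """Convenience: join, compute daily rates, frame sparse dates."""
    return frame_sparse_dates(daily_rates(attach_dates(comments, codes)), min_comments)


def yearly_summary(coded: Sequence[DatedLabels]) -> pd.DataFrame:
    """Per-year counts and percentages of each coding category.

    A multi-label comment counts once under every label it carries, so the
    nine counts can sum to more than that year's N; percentages are of the
    year's total comment count, rounded to one decimal for reporting.
    """
    rows = []
    year_n: dict[int, int] = {}
    for item in coded:
        year = item.date.year
        year_n[year] = year_n.get(year, 0) + 1
        for lab in item.labels:
            rows.append({"year": year, "category": lab})
    if not rows:
        return pd.DataFrame(columns=["year", "category", "count", "n", "percent"])
    df = pd.DataFrame(rows)
    counts = df.groupby(["year", "category"]).size()
    out = []
    for year in sorted(year_n):
        for cat in CATEGORIES:
            c = int(counts.get((year, cat), 0))
            out.append(
                {
                    "year": year,
                    "category": cat,
                    "count": c,
                    "n": year_n[year],
                    "percent": round(100.0 * c / year_n[year], 1),
                }
            )
    return pd.DataFrame(out)
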