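"""Readers and writers for all pipeline artifacts.

Comments and codings are stored as UTF-8 JSON-lines records; policies, rate
series and fit tables as CSV with a header.  Readers validate and reject
malformed input (citing the offending line) rather than repairing it;
writers emit records in a deterministic order so reruns are byte-identical.
Field names are documented in docs/formats.md.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .categories import CATEGORIES, validate_labels
from .types import Comment, CodedComment, PolicyEvent, SegmentedFit, SeriesPoint


class CorpusFormatError(ValueError):
    """Raised when an on-disk artifact violates its documented format."""


def _parse_date(value: str, where: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise CorpusFormatError(f"{where}: unparseable date {value!r}") from exc


# ---------------------------------------------------------------------------
# comments (JSON lines)

def write_comments(comments: Iterable[Comment], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in comments:
            rec = {
                "comment_id": c.comment_id,
                "case_id": c.case_id,
                "media_source": c.media_source,
                "date": c.date.isoformat(),
                "text": c.text,
                "flags": sorted(c.flags),
            }
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")


def read_comments(path) -> list[Comment]:
    comments: list[Comment] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}, line {lineno}: invalid JSON") from exc
            try:
                cid = rec["comment_id"]
                comment = Comment(
                    comment_id=cid,
                    case_id=rec["case_id"],
                    media_source=rec["media_source"],
                    date=_parse_date(rec["date"], f"{path}, line {lineno}"),
                    text=rec["text"],
                    flags=frozenset(rec.get("flags", ())),
                )
            except KeyError as exc:
                raise CorpusFormatError(
                    f"{path}, line {lineno}: missing field {exc}"
                ) from exc
            if cid in seen:
                raise CorpusFormatError(
                    f"{path}, line {lineno}: duplicate comment_id {cid!r}"
                )
            seen.add(cid)
            comments.append(comment)
    return comments


# ---------------------------------------------------------------------------
# codings (JSON lines)

def write_codes(codes: Iterable[CodedComment], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in codes:
            rec = {
                "comment_id": c.comment_id,
                "labels": sorted(c.labels),
                "rater_id": c.rater_id,
            }
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")


def read_codes(path) -> list[CodedComment]:
    codes: list[CodedComment] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"{path}, line {lineno}: invalid JSON") from exc
            try:
                labels = validate_labels(rec["labels"])
            except ValueError as exc:
                raise CorpusFormatError(f"{path}, line {lineno}: {exc}") from exc
            codes.append(
                CodedComment(
                    comment_id=rec["comment_id"],
                    labels=labels,
                    rater_id=rec.get("rater_id"),
                )
            )
    return codes


# ---------------------------------------------------------------------------
# policies (CSV)

POLICY_COLUMNS = ["policy_id", "promulgation_date", "lag_days", "title"]


def write_policies(policies: Iterable[PolicyEvent], path) -> None:
    rows = [
        {
            "policy_id": p.policy_id,
            "promulgation_date": p.promulgation_date.isoformat(),
            "lag_days": p.lag_days,
            "title": p.title,
        }
        for p in policies
    ]
    pd.DataFrame(rows, columns=POLICY_COLUMNS).to_csv(path, index=False)


def read_policies(path) -> list[PolicyEvent]:
    """Read a policy table, returned sorted ascending by promulgation date."""
    df = pd.read_csv(path, dtype={"title": str}, keep_default_na=False)
    missing = set(POLICY_COLUMNS[:2]) - set(df.columns)
    if missing:
        raise CorpusFormatError(f"{path}: missing columns {sorted(missing)}")
    policies = []
    for i, row in df.iterrows():
        policies.append(
            PolicyEvent(
                policy_id=int(row["policy_id"]),
                promulgation_date=_parse_date(
                    row["promulgation_date"], f"{path}, row {i + 1}"
                ),
                lag_days=int(row["lag_days"]) if "lag_days" in df.columns else 0,
                title=str(row.get("title", "")),
            )
        )
    policies.sort(key=lambda p: p.promulgation_date)
    dates = [p.promulgation_date for p in policies]
    if len(set(dates)) != len(dates):
        raise CorpusFormatError(f"{path}: policy dates must be distinct")
    return policies


# ---------------------------------------------------------------------------
# rate series (CSV)

SERIES_COLUMNS = ["t", "date", "support_rate", "blame_rate", "n_comments", "framed"]


def write_series(points: Sequence[SeriesPoint], path) -> None:
    rows = [
        {
            "t": p.t,
            "date": p.date.isoformat(),
            "support_rate": repr(p.support_rate),
            "blame_rate": repr(p.blame_rate),
            "n_comments": p.n_comments,
            "framed": p.framed,
        }
        for p in points
    ]
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)


def read_series(path) -> list[SeriesPoint]:
    df = pd.read_csv(path)
    points = []
    for i, row in df.iterrows():
        points.append(
            SeriesPoint(
                t=int(row["t"]),
                date=_parse_date(row["date"], f"{path}, row {i + 1}"),
                support_rate=float(row["support_rate"]),
                blame_rate=float(row["blame_rate"]),
                n_comments=int(row["n_comments"]),
                framed=bool(row["framed"]),
            )
        )
    return points


# ---------------------------------------------------------------------------
# segmented fits (CSV, leading columns in the published table layout:
# policy, policy date, beta1, P, beta2, P, beta3, P)

FIT_COLUMNS = [
    "policy", "policy_date",
    "beta1", "p_beta1", "beta2", "p_beta2", "beta3", "p_beta3",
    "beta0", "p_beta0",
    "se_beta0", "se_beta1", "se_beta2", "se_beta3",
    "outcome", "error_model", "arma_p", "arma_q",
    "n_points", "window_start", "window_end",
]


def write_fits(fits: Sequence[SegmentedFit], path) -> None:
    rows = []
    for f in fits:
        p0, p1, p2, p3 = f.pvalues
        s0, s1, s2, s3 = f.se
        rows.append(
            {
                "policy": f.policy_id,
                "policy_date": f.policy_date.isoformat(),
                "beta1": repr(f.beta1), "p_beta1": repr(p1),
                "beta2": repr(f.beta2), "p_beta2": repr(p2),
                "beta3": repr(f.beta3), "p_beta3": repr(p3),
                "beta0": repr(f.beta0), "p_beta0": repr(p0),
                "se_beta0": repr(s0), "se_beta1": repr(s1),
                "se_beta2": repr(s2), "se_beta3": repr(s3),
                "outcome": f.outcome,
                "error_model": f.error_model,
                "arma_p": f.arma_order[0] if f.arma_order else "",
                "arma_q": f.arma_order[1] if f.arma_order else "",
                "n_points": f.n_points,
                "window_start": f.window[0],
                "window_end": f.window[1],
            }
        )
    pd.DataFrame(rows, columns=FIT_COLUMNS).to_csv(path, index=False)


def read_fits(path) -> list[SegmentedFit]:
    df = pd.read_csv(path)
    fits = []
    for i, row in df.iterrows():
        has_order = row.notna().get("arma_p", False) and str(row.get("arma_p")) != ""
        fits.append(
            SegmentedFit(
                policy_id=int(row["policy"]),
                policy_date=_parse_date(row["policy_date"], f"{path}, row {i + 1}"),
                outcome=str(row["outcome"]),
                beta0=float(row["beta0"]),
                beta1=float(row["beta1"]),
                beta2=float(row["beta2"]),
                beta3=float(row["beta3"]),
                se=tuple(float(row[f"se_beta{k}"]) for k in range(4)),
                pvalues=tuple(float(row[f"p_beta{k}"]) for k in range(4)),
                window=(int(row["window_start"]), int(row["window_end"])),
                n_points=int(row["n_points"]),
                error_model=str(row["error_model"]),
                arma_order=(int(row["arma_p"]), int(row["arma_q"])) if has_order else None,
            )
        )
    return fits


def valid_category_names() -> list[str]:
    return list(CATEGORIES)
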