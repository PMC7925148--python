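"""Sampling, cleaning, interrater reliability and consensus resolution.

Implements the corpus QC protocol: chronological area sampling with a
400-comment cap per case, duplicate elimination, the 20% meaningless-refill
rule, exact-match interrater reliability with a 0.9 calibration threshold,
and per-category majority consensus with ties escalated for human
adjudication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .categories import NA
from .types import CodedComment, Comment, SamplingReport

logger = logging.getLogger(__name__)


def _sorted_chronologically(comments: Sequence[Comment]) -> list[Comment]:
    return sorted(comments, key=lambda c: (c.date, c.comment_id))


def area_partition(n: int, n_areas: int) -> list[tuple[int, int]]:
    """Split ``n`` chronologically ordered items into ``n_areas`` contiguous
    areas; the remainder is spread over the last areas (one extra each)."""
    base, rem = divmod(n, n_areas)
    sizes = [base] * (n_areas - rem) + [base + 1] * rem
    bounds, start = [], 0
    for s in sizes:
        bounds.append((start, start + s))
        start += s
    return bounds


def area_sample(
    comments: Sequence[Comment], cap: int = 400, seed: int | None = None
) -> tuple[list[Comment], SamplingReport]:
    """Chronological area sampling with a hard cap.

    If the corpus does not exceed ``cap`` comments, everything is kept.
    Otherwise the comments are sorted by date, partitioned into ``cap/2``
    contiguous equal-size areas, and 2 comments are drawn uniformly without
    replacement from each area, yielding exactly ``cap`` comments spread
    over the whole period.
    """
    if cap <= 0 or cap % 2:
        raise ValueError("cap must be a positive even integer")
    ordered = _sorted_chronologically(comments)
    n = len(ordered)
    if n <= cap:
        return list(ordered), SamplingReport(n_input=n, n_after_dedup=n, n_sampled=n)
    n_areas = cap // 2
    rng = np.random.default_rng(seed)
    chosen: list[Comment] = []
    for start, stop in area_partition(n, n_areas):
        idx = rng.choice(np.arange(start, stop), size=2, replace=False)
        chosen.extend(ordered[i] for i in sorted(idx))
    report = SamplingReport(
        n_input=n, n_after_dedup=n, n_sampled=len(chosen), areas_used=n_areas
    )
    return chosen, report


def deduplicate(comments: Sequence[Comment]) -> list[Comment]:
    """Drop comments whose text exactly repeats an earlier comment in the
    same case (the first occurrence, in date order, is kept)."""
    seen: set[tuple[str, str]] = set()
    out = []
    for c in _sorted_chronologically(comments):
        key = (c.case_id, c.text)
        if key in seen:
            continue
        seen.add(key)
        out.append(c)
    return out


def clean_sample(
    sampled: Sequence[Comment],
    meaningless_predicate: Callable[[Comment], bool],
    refill_pool: Sequence[Comment] = (),
    threshold: float = 0.20,
    seed: int | None = None,
) -> tuple[list[Comment], SamplingReport]:
    """Deduplicate, then apply the meaningless-refill rule.

    Exact duplicates are removed first.  If the fraction of meaningless
    comments then *exceeds* ``threshold`` (strictly), the meaningless
    comments are removed and replacements are drawn from the unused pool by
    the same area-sampling method until the target size is restored or the
    pool is exhausted.  At or below the threshold the meaningless comments
    are retained (they are simply coded N/A downstream).
    """
    deduped = deduplicate(sampled)
    n_input = len(sampled)
    target = len(deduped)
    meaningless = [c for c in deduped if meaningless_predicate(c)]
    frac = len(meaningless) / target if target else 0.0
    if frac <= threshold:
        report = SamplingReport(
            n_input=n_input, n_after_dedup=target, n_sampled=target
        )
        return deduped, report

    kept = [c for c in deduped if not meaningless_predicate(c)]
    removed = target - len(kept)
    used_ids = {c.comment_id for c in sampled}
    kept_keys = {(c.case_id, c.text) for c in kept}
    pool = [
        c for c in deduplicate(refill_pool)
        if c.comment_id not in used_ids and (c.case_id, c.text) not in kept_keys
    ]
    refilled = 0
    rng_seed = seed
    while len(kept) < target and pool:
        needed = target - len(kept)
        draw_cap = needed + (needed % 2)
        if len(pool) <= needed:
            drawn, pool = pool, []
        else:
            drawn, _ = area_sample(pool, cap=max(2, draw_cap), seed=rng_seed)
            drawn = drawn[:needed]
            drawn_ids = {c.comment_id for c in drawn}
            pool = [c for c in pool if c.comment_id not in drawn_ids]
        rng_seed = None if rng_seed is None else rng_seed + 1
        for c in drawn:
            if meaningless_predicate(c):
                continue
            key = (c.case_id, c.text)
            if key in kept_keys:
                continue
            kept_keys.add(key)
            kept.append(c)
            refilled += 1
    if len(kept) < target:
        logger.warning(
            "refill pool exhausted: %d of %d comments restored", refilled, removed
        )
    kept = _sorted_chronologically(kept)
    report = SamplingReport(
        n_input=n_input,
        n_after_dedup=target,
        n_sampled=len(kept),
        n_meaningless_removed=removed,
        n_refilled=refilled,
    )
    return kept, report


# ---------------------------------------------------------------------------
# interrater reliability

def _as_map(codes: Sequence[CodedComment]) -> dict[str, frozenset]:
    return {c.comment_id: c.labels for c in codes}


def interrater_reliability(
    codes_a: Sequence[CodedComment], codes_b: Sequence[CodedComment]
) -> float:
    """Share of comments whose label sets agree exactly between two raters."""
    a, b = _as_map(codes_a), _as_map(codes_b)
    if set(a) != set(b):
        raise ValueError("raters coded different comment_id sets")
    if not a:
        raise ValueError("cannot compute reliability on an empty coding table")
    same = sum(a[cid] == b[cid] for cid in a)
    return same / len(a)


def min_pairwise_reliability(tables: Mapping[str, Sequence[CodedComment]]) -> float:
    """Conservative multi-rater reliability: the minimum over all rater pairs."""
    names = sorted(tables)
    if len(names) < 2:
        raise ValueError("need at least two raters")
    return min(
        interrater_reliability(tables[a], tables[b])
        for i, a in enumerate(names)
        for b in names[i + 1:]
    )


@dataclass
class CalibrationResult:
    passed: bool
    reliability: float
    n_used: int
    target: float


def calibration_loop(
    tables: Mapping[str, Sequence[CodedComment]],
    sample_size: int = 50,
    target: float = 0.9,
    seed: int | None = None,
) -> CalibrationResult:
    """Check rater calibration on a random sample of coded comments.

    Reports whether the minimum pairwise reliability on the calibration
    sample reaches ``target`` (0.9 in the protocol).  A failing result means
    the coding team must retrain and recode: the software only measures.
    """
    ids = sorted(set.intersection(*(set(_as_map(t)) for t in tables.values())))
    if not ids:
        raise ValueError("raters share no coded comments")
    if len(ids) < sample_size:
        logger.warning(
            "calibration sample smaller than %d (have %d); using all",
            sample_size, len(ids),
        )
        chosen = ids
    else:
        rng = np.random.default_rng(seed)
        chosen = sorted(rng.choice(ids, size=sample_size, replace=False))
    subset = set(chosen)
    sub_tables = {
        r: [c for c in rows if c.comment_id in subset] for r, rows in tables.items()
    }
    rel = min_pairwise_reliability(sub_tables)
    return CalibrationResult(
        passed=rel >= target, reliability=rel, n_used=len(chosen), target=target
    )


def resolve_consensus(
    tables: Mapping[str, Sequence[CodedComment]],
) -> tuple[list[CodedComment], list[str]]:
    """Merge rater tables into consensus codes.

    Comments on which all raters agree pass through unchanged.  Discordant
    comments are resolved per category by strict majority.  Comments where
    any category splits evenly, or where no label wins a majority, are
    returned separately for human adjudication (re-reading comments cannot
    be automated) and excluded from the consensus output.
    """
    maps = {r: _as_map(t) for r, t in tables.items()}
    raters = sorted(maps)
    ids = sorted(set.union(*(set(m) for m in maps.values())))
    n = len(raters)
    consensus: list[CodedComment] = []
    adjudicate: list[str] = []
    for cid in ids:
        sets = [maps[r][cid] for r in raters if cid in maps[r]]
        if len(sets) < n:
            adjudicate.append(cid)
            continue
        if all(s == sets[0] for s in sets):
            consensus.append(CodedComment(cid, sets[0]))
            continue
        votes: dict[str, int] = {}
        for s in sets:
            for lab in s:
                votes[lab] = votes.get(lab, 0) + 1
        if any(2 * v == n for v in votes.values()):
            adjudicate.append(cid)
            continue
        majority = {lab for lab, v in votes.items() if 2 * v > n}
        if NA in majority and len(majority) > 1:
            majority.discard(NA)
        if not majority:
            adjudicate.append(cid)
            continue
        consensus.append(CodedComment(cid, frozenset(majority)))
    return consensus, adjudicate
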