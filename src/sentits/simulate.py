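"""Synthetic comment streams with a known piecewise-linear sentiment process.

The crawled media comments the analysis was designed for are not publicly
deposited, so every downstream stage is exercised on simulated corpora whose
statistical structure matches what the analysis assumes: a latent daily
probability vector over the nine coding categories whose two merged rates
("support doctor", "blame doctor") follow a piecewise-linear trend with a
level and slope discontinuity at each policy date plus stationary AR(1)
noise; comment counts per day from an overdispersed count distribution so
sparse dates occur; bag-of-words comment text drawn from per-category
lexicons; and configurable duplicate/"meaningless" contamination and
imperfect rater agreement.

All randomness flows from ``SyntheticConfig.seed``: the same configuration
always yields a byte-identical corpus.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .categories import (
    BLAME_GROUP,
    CATEGORIES,
    CATEGORY_INDEX,
    NA,
    OTHER_GROUP,
    SUPPORT_GROUP,
)
from .types import CodedComment, Comment, PolicyEvent, SeriesPoint

logger = logging.getLogger(__name__)

MEDIA_SOURCES = (
    "Tencent News", "Sohu News", "iFeng News",
    "Sina News", "Tianya Forum", "NetEase News",
)

# Category shares pooled over the hand-coded years of the study period
# (2011-2016); used as the default latent baseline.
DEFAULT_BASELINE = {
    "Blame Big System": 0.0816,
    "Blame Medical System": 0.0427,
    "Blame Doctor": 0.1648,
    "Blame Patient": 0.1638,
    "Blame Other": 0.0190,
    "Support Doctor": 0.1719,
    "Support Patient": 0.0359,
    "Support Other": 0.0008,
    "N/A": 0.3195,
}


def default_lexicons(words_per_category: int = 20, shared: int = 8) -> dict[str, dict[str, float]]:
    """Per-category token lexicons: mostly category-specific tokens plus a
    small shared pool, so categories are separable but not trivially so."""
    slugs = {c: c.lower().replace(" ", "").replace("/", "") for c in CATEGORIES}
    shared_words = {f"common{k}": 0.5 for k in range(shared)}
    lex = {}
    for c in CATEGORIES:
        own = {f"{slugs[c]}_{k}": 1.0 for k in range(words_per_category)}
        lex[c] = {**own, **shared_words}
    return lex


def default_offtopic_lexicon(n: int = 15) -> dict[str, float]:
    return {f"offtopic_{k}": 1.0 for k in range(n)}


@dataclass(frozen=True)
class PolicyEffect:
    """Level/slope discontinuities a policy induces in the merged rates.

    ``support_dlevel``/``support_dslope`` act on the combined support-doctor
    rate; the blame effects act on the combined blame-doctor rate (typically
    with the opposite sign).  Slopes are per day of the latent process.
    """

    support_dlevel: float = 0.0
    support_dslope: float = 0.0
    blame_dlevel: float = 0.0
    blame_dslope: float = 0.0


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic corpus.

    Defaults emulate the conditions of the analysed decade: comments on
    media reports between late 2011 and spring 2020, a handful of comments
    per day on average with heavy overdispersion (most dates sparse, report
    days bursty), category baseline from the pooled hand-coded shares, and
    four raters calibrated to 0.9 agreement.
    """

    seed: int = 0
    start: dt.date = dt.date(2011, 10, 19)
    end: dt.date = dt.date(2020, 4, 4)
    comments_per_day_mean: float = 6.0
    comments_per_day_dispersion: float | None = 0.5
    category_baseline: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE)
    )
    support_slope: float = 0.0
    blame_slope: float = 0.0
    policy_effects: Sequence[PolicyEffect] = ()
    ar_phi: float = 0.4
    noise_sd: float = 0.05
    lexicons: Mapping[str, Mapping[str, float]] = field(default_factory=default_lexicons)
    offtopic_lexicon: Mapping[str, float] = field(default_factory=default_offtopic_lexicon)
    comment_length_mean: float = 8.0
    comment_length_dispersion: float | None = 5.0
    duplicate_rate: float = 0.05
    meaningless_rate: float = 0.10
    second_label_rate: float = 0.15
    rater_agreement: float = 0.9
    n_raters: int = 4
    n_cases: int = 17
    exact_allocation: bool = False

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("date_span is empty")
        probs = np.array([self.category_baseline.get(c, 0.0) for c in CATEGORIES])
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("category_baseline must be a probability vector over the 9 categories")
        if not -1.0 < self.ar_phi < 1.0:
            raise ValueError("ar_phi must lie in (-1, 1)")
        for name in ("duplicate_rate", "meaningless_rate", "second_label_rate",
                     "rater_agreement"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_raters < 2:
            raise ValueError("n_raters must be >= 2")

    @property
    def baseline_vector(self) -> np.ndarray:
        return np.array([self.category_baseline.get(c, 0.0) for c in CATEGORIES], dtype=float)

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for one stage, derived from the master seed."""
        return np.random.default_rng([int(self.seed) % (2**31), stream])


@dataclass
class LatentTrajectory:
    """Per-day latent category probabilities and the two merged rates."""

    dates: list[dt.date]
    probs: np.ndarray          # shape (n_days, 9); rows sum to 1
    support: np.ndarray        # merged support-doctor rate per day
    blame: np.ndarray          # merged blame-doctor rate per day

    def day_index(self, date: dt.date) -> int:
        return (date - self.dates[0]).days

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.probs, index=self.dates, columns=list(CATEGORIES))
        df["support_rate"] = self.support
        df["blame_rate"] = self.blame
        return df


def generate_policy_schedule(config: SyntheticConfig, n_policies: int) -> list[PolicyEvent]:
    """Draw ``n_policies`` strictly increasing promulgation dates in the span."""
    if n_policies < 0:
        raise ValueError("n_policies must be >= 0")
    if n_policies == 0:
        return []
    span_days = (config.end - config.start).days + 1
    # keep interventions away from the edges so each has pre/post room
    margin = max(1, span_days // 10)
    candidates = np.arange(margin, span_days - margin)
    if len(candidates) < n_policies:
        raise ValueError(
            f"date span too short to place {n_policies} distinct policy dates"
        )
    rng = config.rng(1)
    offsets = np.sort(rng.choice(candidates, size=n_policies, replace=False))
    return [
        PolicyEvent(
            policy_id=i + 1,
            promulgation_date=config.start + dt.timedelta(days=int(off)),
            lag_days=0,
            title=f"policy {i + 1}",
        )
        for i, off in enumerate(offsets)
    ]


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        eps[t] = phi * eps[t - 1] + shocks[t - 1]
    return eps


def generate_latent_rates(
    config: SyntheticConfig, schedule: Sequence[PolicyEvent]
) -> LatentTrajectory:
    """Build the per-day latent category-probability trajectory.

    The merged support rate follows
    ``baseline + slope*t + sum over active policies of
    [dlevel + dslope * (days since the lagged policy date + 1)] + AR(1) noise``
    (the trend term counts the policy day itself as 1, matching the
    segmented-regression design used downstream), and likewise for the
    merged blame rate.  Each day's category vector scales the two merged
    groups to their target rates and spreads the residual mass
    proportionally over the remaining categories, then clips to [0, 1] and
    renormalizes.
    """
    n_days = (config.end - config.start).days + 1
    dates = [config.start + dt.timedelta(days=i) for i in range(n_days)]
    for p in schedule:
        if not (config.start <= p.promulgation_date <= config.end):
            raise ValueError(f"policy {p.policy_id} date outside the configured span")

    base = config.baseline_vector
    sup_idx = [CATEGORY_INDEX[c] for c in sorted(SUPPORT_GROUP)]
    blm_idx = [CATEGORY_INDEX[c] for c in sorted(BLAME_GROUP)]
    oth_idx = [CATEGORY_INDEX[c] for c in sorted(OTHER_GROUP)]
    base_sup, base_blm = base[sup_idx].sum(), base[blm_idx].sum()
    base_oth = base[oth_idx].sum()

    t = np.arange(n_days, dtype=float)
    support = base_sup + config.support_slope * t
    blame = base_blm + config.blame_slope * t
    effects = list(config.policy_effects) + [PolicyEffect()] * (
        len(schedule) - len(config.policy_effects)
    )
    for policy, eff in zip(schedule, effects):
        k0 = (policy.effect_date - config.start).days
        active = t >= k0
        since = np.where(active, t - k0 + 1.0, 0.0)
        support = support + active * eff.support_dlevel + since * eff.support_dslope
        blame = blame + active * eff.blame_dlevel + since * eff.blame_dslope

    rng = config.rng(2)
    support = support + _ar1(rng, n_days, config.ar_phi, config.noise_sd)
    blame = blame + _ar1(rng, n_days, config.ar_phi, config.noise_sd)

    clipped = ((support < 0) | (support > 1) | (blame < 0) | (blame > 1)).sum()
    if clipped:
        logger.warning(
            "latent merged rates clipped to [0, 1] on %d of %d days", clipped, n_days
        )
    support = np.clip(support, 0.0, 1.0)
    blame = np.clip(blame, 0.0, 1.0)

    probs = np.empty((n_days, len(CATEGORIES)))
    with np.errstate(invalid="ignore", divide="ignore"):
        probs[:, sup_idx] = np.outer(
            support, base[sup_idx] / base_sup if base_sup > 0 else
            np.full(len(sup_idx), 1.0 / len(sup_idx))
        )
        probs[:, blm_idx] = np.outer(
            blame, base[blm_idx] / base_blm if base_blm > 0 else
            np.full(len(blm_idx), 1.0 / len(blm_idx))
        )
        other = np.clip(1.0 - support - blame, 0.0, None)
        probs[:, oth_idx] = np.outer(
            other, base[oth_idx] / base_oth if base_oth > 0 else
            np.full(len(oth_idx), 1.0 / len(oth_idx))
        )
    probs = np.clip(probs, 0.0, 1.0)
    probs /= probs.sum(axis=1, keepdims=True)
    support = probs[:, sup_idx].sum(axis=1)
    blame = probs[:, blm_idx].sum(axis=1)
    return LatentTrajectory(dates=dates, probs=probs, support=support, blame=blame)


def series_from_latent(latent: LatentTrajectory, n_comments: int = 1) -> list[SeriesPoint]:
    """Expose the latent merged rates directly as an analysis series
    (one point per day), bypassing comment sampling."""
    return [
        SeriesPoint(
            t=i,
            date=d,
            support_rate=float(latent.support[i]),
            blame_rate=float(latent.blame[i]),
            n_comments=n_comments,
        )
        for i, d in enumerate(latent.dates)
    ]


def _draw_count(rng, mean: float, dispersion: float | None) -> int:
    if mean <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(mean))
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _largest_remainder(counts_target: np.ndarray, n: int) -> np.ndarray:
    """Apportion n items over categories proportionally (largest remainder)."""
    raw = counts_target * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def generate_comments(
    config: SyntheticConfig, latent: LatentTrajectory
) -> tuple[list[Comment], list[CodedComment]]:
    """Sample the comment stream from the latent trajectory.

    Returns the comments plus their ground-truth label sets.  Meaningless
    comments draw off-topic tokens and carry truth N/A; duplicates copy an
    earlier comment's text and labels.  Both are flagged so the cleaning
    stage can be validated against the truth.
    """
    for c, p in zip(CATEGORIES, config.baseline_vector):
        if p > 0 and not config.lexicons.get(c):
            raise ValueError(f"category {c!r} has probability mass but an empty lexicon")
    rng = config.rng(3)
    lex_words = {c: list(config.lexicons.get(c, {})) for c in CATEGORIES}
    lex_probs = {}
    for c in CATEGORIES:
        w = np.array([config.lexicons[c][t] for t in lex_words[c]], dtype=float) \
            if lex_words[c] else np.array([])
        lex_probs[c] = w / w.sum() if w.size else w
    off_words = list(config.offtopic_lexicon)
    off_w = np.array([config.offtopic_lexicon[t] for t in off_words], dtype=float)
    off_probs = off_w / off_w.sum() if off_w.size else off_w

    n_days = len(latent.dates)
    case_bounds = np.linspace(0, n_days, config.n_cases + 1)

    comments: list[Comment] = []
    truth: list[CodedComment] = []
    counter = 0

    def draw_text(labels: frozenset, length: int) -> str:
        labs = sorted(labels)
        toks = []
        for _ in range(length):
            lab = labs[rng.integers(len(labs))] if len(labs) > 1 else labs[0]
            words, probs = lex_words[lab], lex_probs[lab]
            toks.append(words[rng.choice(len(words), p=probs)])
        return " ".join(toks)

    for day, date in enumerate(latent.dates):
        n = _draw_count(rng, config.comments_per_day_mean, config.comments_per_day_dispersion)
        if n == 0:
            continue
        case_id = f"C{int(np.searchsorted(case_bounds, day, side='right'))}"
        pvec = latent.probs[day]
        if config.exact_allocation:
            alloc = _largest_remainder(pvec, n)
            primaries = np.repeat(np.arange(len(CATEGORIES)), alloc)
        else:
            primaries = rng.choice(len(CATEGORIES), size=n, p=pvec)
        for primary in primaries:
            counter += 1
            cid = f"S{counter:07d}"
            media = MEDIA_SOURCES[rng.integers(len(MEDIA_SOURCES))]
            length = max(1, _draw_count(rng, config.comment_length_mean,
                                        config.comment_length_dispersion))
            if rng.random() < config.meaningless_rate and off_words:
                toks = [off_words[rng.choice(len(off_words), p=off_probs)]
                        for _ in range(length)]
                comments.append(Comment(cid, case_id, media, date, " ".join(toks),
                                        frozenset({"meaningless"})))
                truth.append(CodedComment(cid, frozenset({NA})))
                continue
            if comments and rng.random() < config.duplicate_rate:
                j = int(rng.integers(len(comments)))
                src = comments[j]
                comments.append(Comment(cid, case_id, media, date, src.text,
                                        src.flags | {"duplicate"}))
                truth.append(CodedComment(cid, truth[j].labels))
                continue
            labels = {CATEGORIES[primary]}
            if CATEGORIES[primary] != NA and rng.random() < config.second_label_rate:
                # second label drawn from the day vector excluding N/A and the primary
                q = pvec.copy()
                q[CATEGORY_INDEX[NA]] = 0.0
                q[primary] = 0.0
                if q.sum() > 0:
                    labels.add(CATEGORIES[rng.choice(len(CATEGORIES), p=q / q.sum())])
            labels = frozenset(labels)
            comments.append(Comment(cid, case_id, media, date, draw_text(labels, length)))
            truth.append(CodedComment(cid, labels))
    return comments, truth


def _perturb_labels(rng: np.random.Generator, truth: frozenset) -> frozenset:
    """Replace a label set with a single label drawn uniformly from the
    categories that would not reproduce the truth."""
    if len(truth) == 1:
        only = next(iter(truth))
        others = [c for c in CATEGORIES if c != only]
        return frozenset({others[rng.integers(len(others))]})
    return frozenset({CATEGORIES[rng.integers(len(CATEGORIES))]})


def generate_rater_codes(
    truth: Sequence[CodedComment], config: SyntheticConfig
) -> dict[str, list[CodedComment]]:
    """Simulate ``n_raters`` independent coders.

    Each rater reproduces a comment's true label set with probability
    ``rater_agreement``; otherwise the set is replaced by a single random
    wrong-ish label (a crude but enumerable error model).
    """
    rng = config.rng(4)
    tables: dict[str, list[CodedComment]] = {}
    for r in range(config.n_raters):
        rid = f"R{r + 1}"
        rows = []
        for tc in truth:
            if rng.random() < config.rater_agreement:
                labels = tc.labels
            else:
                labels = _perturb_labels(rng, tc.labels)
            rows.append(CodedComment(tc.comment_id, labels, rater_id=rid))
        tables[rid] = rows
    return tables
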