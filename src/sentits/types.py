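"""Shared domain records passed between pipeline stages."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

from .categories import validate_labels

VALID_FLAGS = frozenset({"duplicate", "meaningless"})


@dataclass(frozen=True)
class Comment:
    """One dated media comment.

    ``flags`` carries synthetic ground truth only (whether the record was
    injected as a duplicate or an off-topic "meaningless" comment); real
    corpora leave it empty.
    """

    comment_id: str
    case_id: str
    media_source: str
    date: dt.date
    text: str
    flags: frozenset = frozenset()

    def __post_init__(self):
        bad = set(self.flags) - VALID_FLAGS
        if bad:
            raise ValueError(f"unknown flags {sorted(bad)}")


@dataclass(frozen=True)
class CodedComment:
    """A comment's label set as assigned by one rater (or by consensus)."""

    comment_id: str
    labels: frozenset
    rater_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "labels", validate_labels(self.labels))


@dataclass(frozen=True)
class PolicyEvent:
    """A central-government policy promulgation used as an interruption point."""

    policy_id: int
    promulgation_date: dt.date
    lag_days: int = 0
    title: str = ""

    def __post_init__(self):
        if self.lag_days < 0:
            raise ValueError("lag_days must be >= 0")

    @property
    def effect_date(self) -> dt.date:
        """Promulgation date shifted by the configured lag."""
        return self.promulgation_date + dt.timedelta(days=self.lag_days)


@dataclass(frozen=True)
class SeriesPoint:
    """One analysis time point: merged sentiment rates at a representative date."""

    t: int
    date: dt.date
    support_rate: float
    blame_rate: float
    n_comments: int
    framed: bool = False

    def __post_init__(self):
        if not (0.0 <= self.support_rate <= 1.0 and 0.0 <= self.blame_rate <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        if self.n_comments < 1:
            raise ValueError("n_comments must be >= 1")


@dataclass
class SegmentedFit:
    """Segmented-regression estimates for one policy and one outcome.

    beta0/beta1 are the baseline level and per-point trend; beta2 is the
    level change at the intervention point and beta3 the per-point trend
    change after it.
    """

    policy_id: int
    policy_date: dt.date
    outcome: str
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    se: tuple[float, float, float, float]
    pvalues: tuple[float, float, float, float]
    window: tuple[int, int]
    n_points: int
    error_model: str = "iid"
    arma_order: tuple[int, int] | None = None
    intervention_t: int | None = None
    durbin_watson: float | None = None
    ljung_box_min_p: float | None = None

    def significant(self, alpha: float = 0.05) -> dict[str, bool]:
        names = ("beta0", "beta1", "beta2", "beta3")
        return {n: (p == p and p < alpha) for n, p in zip(names, self.pvalues)}


@dataclass
class SamplingReport:
    """Bookkeeping counts for the area-sampling and cleaning steps."""

    n_input: int = 0
    n_after_dedup: int = 0
    n_sampled: int = 0
    n_meaningless_removed: int = 0
    n_refilled: int = 0
    areas_used: int = 0

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DatedLabels:
    """A comment's consensus labels joined with its calendar date."""

    comment_id: str
    date: dt.date
    labels: frozenset = field(default_factory=frozenset)
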