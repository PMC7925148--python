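"""Simulation studies validating the estimator and the classifier.

These are the package's built-in calibration checks: parameter recovery and
confidence-interval coverage of the segmented regression on synthetic AR(1)
series with known level/slope changes, its type-I error under a null series,
and held-out accuracy of the dictionary classifier on a corpus with
category-specific lexicons.  Both the test suite and the acceptance script
run them through this module so the study conditions are defined once.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .categories import NA
from .sentiment import build_dictionary, score_and_classify
from .simulate import (
    PolicyEffect,
    SyntheticConfig,
    default_lexicons,
    generate_comments,
    generate_latent_rates,
    series_from_latent,
)
from .itsa import fit_segmented
from .types import PolicyEvent

logger = logging.getLogger(__name__)

# Baseline with moderate merged rates (support 0.20, blame 0.15) so that a
# +0.15 level change plus 30 points of +0.01/day trend stays inside [0, 1]
# with 3-sigma noise headroom and the latent process is never clipped in
# the fitted window.
STUDY_BASELINE = {
    "Blame Big System": 0.14,
    "Blame Medical System": 0.10,
    "Blame Doctor": 0.10,
    "Blame Patient": 0.08,
    "Blame Other": 0.05,
    "Support Doctor": 0.12,
    "Support Patient": 0.05,
    "Support Other": 0.05,
    "N/A": 0.31,
}

STUDY_START = dt.date(2015, 1, 1)
STUDY_DAYS = 200
STUDY_POLICY_DAY = 165     # 35 post days, of which the fit window uses 30
TRUE_DLEVEL = 0.15
TRUE_DSLOPE = 0.01
STUDY_PHI = 0.4
STUDY_NOISE_SD = 0.05


@dataclass
class RecoveryResult:
    n_replicates: int
    mean_beta2: float
    mean_beta3: float
    sd_beta2: float
    sd_beta3: float
    mc_se_beta2: float
    mc_se_beta3: float
    coverage_beta2: float
    coverage_beta3: float
    true_dlevel: float = TRUE_DLEVEL
    true_dslope: float = TRUE_DSLOPE


def _study_policy() -> PolicyEvent:
    return PolicyEvent(1, STUDY_START + dt.timedelta(days=STUDY_POLICY_DAY))


def _study_config(seed: int, with_effect: bool, phi: float) -> SyntheticConfig:
    effects = (
        [PolicyEffect(support_dlevel=TRUE_DLEVEL, support_dslope=TRUE_DSLOPE)]
        if with_effect
        else []
    )
    return SyntheticConfig(
        seed=seed,
        start=STUDY_START,
        end=STUDY_START + dt.timedelta(days=STUDY_DAYS - 1),
        noise_sd=STUDY_NOISE_SD,
        ar_phi=phi,
        category_baseline=dict(STUDY_BASELINE),
        policy_effects=effects,
    )


def recovery_study(n_replicates: int = 500, seed: int = 0) -> RecoveryResult:
    """Recover a known (level, slope) change from AR(1) series.

    Each replicate simulates a 200-day latent series with a +0.15 level and
    +0.01/day slope change at day 165 under AR(1) noise (phi 0.4, marginal
    sd 0.05), fits the segmented model, and records the estimates and
    whether the 95% CI covers the truth.
    """
    policy = _study_policy()
    z = stats.norm.ppf(0.975)
    b2, b3, cov2, cov3 = [], [], [], []
    for r in range(n_replicates):
        cfg = _study_config(seed * n_replicates + r, True, STUDY_PHI)
        latent = generate_latent_rates(cfg, [policy])
        fit = fit_segmented(series_from_latent(latent), policy, "support_rate")
        b2.append(fit.beta2)
        b3.append(fit.beta3)
        cov2.append(abs(fit.beta2 - TRUE_DLEVEL) <= z * fit.se[2])
        cov3.append(abs(fit.beta3 - TRUE_DSLOPE) <= z * fit.se[3])
    b2, b3 = np.asarray(b2), np.asarray(b3)
    return RecoveryResult(
        n_replicates=n_replicates,
        mean_beta2=float(b2.mean()),
        mean_beta3=float(b3.mean()),
        sd_beta2=float(b2.std(ddof=1)),
        sd_beta3=float(b3.std(ddof=1)),
        mc_se_beta2=float(b2.std(ddof=1) / np.sqrt(n_replicates)),
        mc_se_beta3=float(b3.std(ddof=1) / np.sqrt(n_replicates)),
        coverage_beta2=float(np.mean(cov2)),
        coverage_beta3=float(np.mean(cov3)),
    )


def type1_study(n_replicates: int = 500, seed: int = 0, alpha: float = 0.05) -> dict:
    """Rejection rates of beta2/beta3 on null series of independent noise."""
    policy = _study_policy()
    rej2 = rej3 = 0
    for r in range(n_replicates):
        cfg = _study_config(10_000_000 + seed * n_replicates + r, False, 0.0)
        latent = generate_latent_rates(cfg, [policy])
        fit = fit_segmented(series_from_latent(latent), policy, "support_rate")
        rej2 += fit.pvalues[2] < alpha
        rej3 += fit.pvalues[3] < alpha
    return {
        "n_replicates": n_replicates,
        "alpha": alpha,
        "type1_beta2": rej2 / n_replicates,
        "type1_beta3": rej3 / n_replicates,
    }


def classifier_study(seed: int = 0, n_holdout: int = 1000) -> dict:
    """Held-out accuracy of the dictionary classifier.

    The corpus uses fully disjoint per-category lexicons (no shared words)
    and clean single-label comments, the regime in which the bag-of-words
    model is identified; accuracy is exact label-set match.
    """
    lex = default_lexicons(words_per_category=20, shared=0)
    cfg = SyntheticConfig(
        seed=seed,
        start=dt.date(2014, 1, 1),
        end=dt.date(2014, 12, 31),
        comments_per_day_mean=9.0,
        comments_per_day_dispersion=None,
        lexicons=lex,
        duplicate_rate=0.0,
        meaningless_rate=0.0,
        second_label_rate=0.0,
        noise_sd=0.05,
    )
    latent = generate_latent_rates(cfg, [])
    comments, truth = generate_comments(cfg, latent)
    if len(comments) < n_holdout + 500:
        raise ValueError("corpus too small for the requested hold-out")
    train_c, train_t = comments[:-n_holdout], truth[:-n_holdout]
    test_c, test_t = comments[-n_holdout:], truth[-n_holdout:]
    dictionary = build_dictionary(list(zip(train_c, train_t)), alpha=1.0)
    correct = 0
    for c, t in zip(test_c, test_t):
        _, labels = score_and_classify(dictionary, c, tau=0.5)
        correct += labels == t.labels
    return {
        "n_train": len(train_c),
        "n_holdout": n_holdout,
        "accuracy": correct / n_holdout,
    }
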