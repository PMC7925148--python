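"""Synthetic corpus generator: determinism, latent process, contamination,
and rater error model."""

import datetime as dt

import numpy as np
import pytest

from sentits import (
    NA,
    PolicyEffect,
    PolicyEvent,
    SyntheticConfig,
    generate_comments,
    generate_latent_rates,
    generate_policy_schedule,
    generate_rater_codes,
)
from sentits.categories import CATEGORIES


def small_config(**kw):
    base = dict(
        seed=11,
        start=dt.date(2014, 1, 1),
        end=dt.date(2014, 12, 31),
        comments_per_day_mean=3.0,
        noise_sd=0.0,
        ar_phi=0.0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestPolicySchedule:
    def test_empty(self):
        assert generate_policy_schedule(small_config(), 0) == []

    def test_cardinality_and_ordering(self):
        cfg = SyntheticConfig(seed=5, start=dt.date(2012, 10, 26), end=dt.date(2019, 3, 5))
        sched = generate_policy_schedule(cfg, 15)
        dates = [p.promulgation_date for p in sched]
        assert len(sched) == 15
        assert all(a < b for a, b in zip(dates, dates[1:]))
        assert all(cfg.start <= d <= cfg.end for d in dates)

    def test_deterministic(self):
        cfg = small_config()
        assert generate_policy_schedule(cfg, 5) == generate_policy_schedule(cfg, 5)

    def test_span_too_short(self):
        cfg = small_config(start=dt.date(2014, 1, 1), end=dt.date(2014, 1, 5))
        with pytest.raises(ValueError):
            generate_policy_schedule(cfg, 50)


class TestLatentRates:
    def test_constant_without_effects(self):
        cfg = small_config()
        latent = generate_latent_rates(cfg, [])
        base_support = cfg.baseline_vector[[5, 3]].sum()  # Support Doctor + Blame Patient
        assert np.allclose(latent.support, base_support, atol=1e-12)

    def test_level_jump_at_policy_day(self):
        cfg = small_config(policy_effects=[PolicyEffect(support_dlevel=0.2)])
        policy = PolicyEvent(1, dt.date(2014, 6, 1))
        latent = generate_latent_rates(cfg, [policy])
        k = latent.day_index(policy.promulgation_date)
        pre, post = latent.support[:k], latent.support[k:]
        assert np.allclose(post - pre[0], 0.2, atol=1e-12)
        assert np.allclose(np.diff(pre), 0, atol=1e-12)
        assert np.allclose(np.diff(post), 0, atol=1e-12)

    def test_rows_sum_to_one(self):
        cfg = small_config(noise_sd=0.08, ar_phi=0.5,
                           policy_effects=[PolicyEffect(support_dlevel=0.1)])
        latent = generate_latent_rates(cfg, [PolicyEvent(1, dt.date(2014, 5, 1))])
        assert np.allclose(latent.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_ar1_autocorrelation_matches_oracle(self):
        # detrended latent support should show lag-1 autocorrelation ~ phi;
        # an independent AR(1) simulation at the same length is the oracle
        phi, sd, n = 0.5, 0.05, 400
        cfg = small_config(
            seed=21, start=dt.date(2014, 1, 1),
            end=dt.date(2014, 1, 1) + dt.timedelta(days=n - 1),
            noise_sd=sd, ar_phi=phi,
        )
        latent = generate_latent_rates(cfg, [])
        x = latent.support - latent.support.mean()

        def lag1(v):
            return float(np.corrcoef(v[:-1], v[1:])[0, 1])

        rng = np.random.default_rng(999)
        eps = np.empty(n)
        eps[0] = rng.normal(0, sd)
        for t in range(1, n):
            eps[t] = phi * eps[t - 1] + rng.normal(0, sd * np.sqrt(1 - phi**2))
        assert abs(lag1(x) - phi) < 0.15
        assert abs(lag1(eps - eps.mean()) - phi) < 0.15

    def test_policy_outside_span_rejected(self):
        with pytest.raises(ValueError):
            generate_latent_rates(small_config(), [PolicyEvent(1, dt.date(2020, 1, 1))])


class TestGenerateComments:
    def test_no_contamination_no_flags(self):
        cfg = small_config(meaningless_rate=0.0, duplicate_rate=0.0)
        comments, truth = generate_comments(cfg, generate_latent_rates(cfg, []))
        assert all(not c.flags for c in comments)
        assert len(comments) == len(truth)

    def test_degenerate_distribution_single_category(self):
        baseline = {c: 0.0 for c in CATEGORIES}
        baseline["Support Doctor"] = 1.0
        cfg = small_config(category_baseline=baseline, meaningless_rate=0.0,
                           duplicate_rate=0.0, second_label_rate=0.0)
        comments, truth = generate_comments(cfg, generate_latent_rates(cfg, []))
        assert all(t.labels == frozenset({"Support Doctor"}) for t in truth)

    def test_label_shares_match_binomial_oracle(self):
        baseline = {c: 0.0 for c in CATEGORIES}
        baseline["Support Doctor"] = 0.5
        baseline["Blame Doctor"] = 0.5
        cfg = small_config(
            seed=17, category_baseline=baseline, comments_per_day_mean=30.0,
            comments_per_day_dispersion=None, meaningless_rate=0.0,
            duplicate_rate=0.0, second_label_rate=0.0,
        )
        _, truth = generate_comments(cfg, generate_latent_rates(cfg, []))
        assert len(truth) > 9000
        share = np.mean([t.labels == frozenset({"Support Doctor"}) for t in truth])
        assert abs(share - 0.5) < 0.02

    def test_contamination_flagged(self):
        cfg = small_config(meaningless_rate=0.3, duplicate_rate=0.2)
        comments, truth = generate_comments(cfg, generate_latent_rates(cfg, []))
        flagged_m = [c for c in comments if "meaningless" in c.flags]
        flagged_d = [c for c in comments if "duplicate" in c.flags]
        assert flagged_m and flagged_d
        by_id = dict(zip([c.comment_id for c in comments], truth))
        assert all(by_id[c.comment_id].labels == frozenset({NA}) for c in flagged_m)

    def test_empty_lexicon_rejected(self):
        lex = {c: {"w": 1.0} for c in CATEGORIES}
        lex["Support Doctor"] = {}
        cfg = small_config(lexicons=lex)
        with pytest.raises(ValueError, match="lexicon"):
            generate_comments(cfg, generate_latent_rates(cfg, []))

    def test_byte_identical_under_same_seed(self):
        cfg = small_config(seed=42)
        a = generate_comments(cfg, generate_latent_rates(cfg, []))
        b = generate_comments(cfg, generate_latent_rates(cfg, []))
        assert a == b


class TestRaterCodes:
    def test_perfect_agreement(self):
        cfg = small_config(rater_agreement=1.0, n_raters=3)
        _, truth = generate_comments(cfg, generate_latent_rates(cfg, []))
        tables = generate_rater_codes(truth, cfg)
        assert len(tables) == 3
        for rows in tables.values():
            assert [r.labels for r in rows] == [t.labels for t in truth]

    def test_agreement_rate_near_configured(self):
        cfg = small_config(seed=3, rater_agreement=0.9, n_raters=2,
                           comments_per_day_mean=2.0)
        _, truth = generate_comments(cfg, generate_latent_rates(cfg, []))
        tables = generate_rater_codes(truth, cfg)
        a, b = tables["R1"], tables["R2"]
        agree = np.mean([x.labels == y.labels for x, y in zip(a, b)])
        # both raters match truth w.p. 0.9 -> pairwise ~ 0.81 + small chance term
        assert abs(agree - (0.81 + 0.19 / 8)) < 0.1

    def test_zero_agreement_matches_enumerated_chance_rate(self):
        # agreement 0: each rater draws one of the 8 other labels uniformly,
        # so two raters coincide with probability exactly 8*(1/8)^2 = 1/8
        baseline = {c: 0.0 for c in CATEGORIES}
        baseline["Support Doctor"] = 1.0
        cfg = small_config(
            seed=9, category_baseline=baseline, rater_agreement=0.0, n_raters=2,
            comments_per_day_mean=20.0, second_label_rate=0.0,
            meaningless_rate=0.0, duplicate_rate=0.0,
        )
        _, truth = generate_comments(cfg, generate_latent_rates(cfg, []))
        tables = generate_rater_codes(truth, cfg)
        agree = np.mean(
            [x.labels == y.labels for x, y in zip(tables["R1"], tables["R2"])]
        )
        assert abs(agree - 1.0 / 8.0) < 0.03
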