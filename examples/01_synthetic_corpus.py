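"""Generate a synthetic comment stream with known sentiment structure.

Builds a one-year corpus whose latent "support doctor" rate jumps by +0.10
at a policy date, with duplicate and off-topic contamination, and prints
what was generated.  Every number is reproducible from the seed.
"""

import datetime as dt

from sentits import (
    PolicyEffect,
    PolicyEvent,
    SyntheticConfig,
    generate_comments,
    generate_latent_rates,
)

cfg = SyntheticConfig(
    seed=7,
    start=dt.date(2014, 1, 1),
    end=dt.date(2014, 12, 31),
    comments_per_day_mean=5.0,
    policy_effects=[PolicyEffect(support_dlevel=0.10, blame_dlevel=-0.05)],
)
policy = PolicyEvent(1, dt.date(2014, 7, 1), title="safety-in-hospitals order")
latent = generate_latent_rates(cfg, [policy])
comments, truth = generate_comments(cfg, latent)

n_dup = sum("duplicate" in c.flags for c in comments)
n_mean = sum("meaningless" in c.flags for c in comments)
k = latent.day_index(policy.promulgation_date)

print(f"generated {len(comments)} comments over {len(latent.dates)} days")
print(f"  duplicates injected: {n_dup}  off-topic (meaningless): {n_mean}")
print(f"latent support rate before policy: {latent.support[k - 1]:.3f}")
print(f"latent support rate at policy day: {latent.support[k]:.3f}")
print("the jump reflects the configured +0.10 level change (plus AR(1) noise)")
print("example comment:", comments[0].date, repr(comments[0].text[:60]))
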