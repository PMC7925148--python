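"""Build the daily sentiment-rate series, framing sparse dates.

Comments are merged into the two analysis outcomes (support doctor = Support
Doctor + Blame Patient; blame doctor = Blame Doctor + Support Patient),
averaged per date, and dates with a single comment are pooled into 3-4 day
frames represented by the frame's second date.
"""

import datetime as dt

from sentits import (
    SyntheticConfig,
    build_series,
    generate_comments,
    generate_latent_rates,
)

cfg = SyntheticConfig(
    seed=3,
    start=dt.date(2014, 1, 1),
    end=dt.date(2014, 12, 31),
    comments_per_day_mean=2.0,       # sparse: many days need framing
    comments_per_day_dispersion=0.4,
)
latent = generate_latent_rates(cfg, [])
comments, truth = generate_comments(cfg, latent)

points = build_series(comments, truth)
framed = [p for p in points if p.framed]
print(f"{len(comments)} comments -> {len(points)} analysis time points "
      f"({len(framed)} pooled from sparse-date frames)")
print(f"comments are conserved: {sum(p.n_comments for p in points)} pooled in total")
for p in points[:5]:
    tag = "frame" if p.framed else "day"
    print(f"  t={p.t:3d} {p.date} [{tag:5s}] n={p.n_comments:2d} "
          f"support={p.support_rate:.2f} blame={p.blame_rate:.2f}")
print("support/blame are the shares of that point's comments on each side")
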