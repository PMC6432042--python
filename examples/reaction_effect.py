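"""Effect of the hydrolysis rate on early and late release times.

The coating hydrolyses autocatalytically at rate k (1/day, applied with a
unit diffusion time so kappa = k numerically).  Faster hydrolysis feeds the
film and accelerates the late stage of release — tau90 falls steadily with
k — while the early stage, over before degradation matters, is nearly
rate-blind: tau30 barely moves.
"""

import numpy as np

from crfrelease import DimensionlessParams, release_time
from crfrelease.profiles import RATE_SET_PER_DAY

t90s, t30s = [], []
print(f"{'k (1/day)':>10} {'tau30':>8} {'tau90':>8}")
for k in RATE_SET_PER_DAY:
    p = DimensionlessParams.from_rate_per_day(
        Dr=1.0, Vr=10.0, l=2.0, Ka=1.0, Kb=1.0, k_per_day=k)
    t30, t90 = release_time(0.30, p), release_time(0.90, p)
    t30s.append(t30)
    t90s.append(t90)
    print(f"{k:>10g} {t30:8.4f} {t90:8.4f}")

sp = lambda v: (max(v) - min(v)) / np.mean(v)
print(f"\nrelative spread across the rate set: "
      f"tau30 {sp(t30s):.2%} vs tau90 {sp(t90s):.2%} — early release is "
      f"diffusion-controlled, late release is reaction-assisted.")
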