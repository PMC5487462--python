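"""Explore the bistable pass/no-pass decision system.

The decision variable obeys xdot = -alpha + x - x^3, with
alpha = (sigma - E/A) * delta.  Between the saddle-node values +-alpha_c
two modes coexist and the previous trial's state decides; sweeping the
target distance up and down therefore flips the decision at different E/A
ratios (hysteresis).
"""

import numpy as np

from passdyn import (
    DecisionParams,
    critical_alpha,
    fixed_points,
    hysteresis_loop,
)

p = DecisionParams()
ac = critical_alpha()
print(f"saddle-node alpha_c    : {ac:.4f} (= 2 / 3*sqrt(3))")
print(f"calibration            : sigma={p.sigma}, delta={p.delta:.3f}")
print(f"analytic thresholds    : up {p.sigma + ac / p.delta:.3f}, "
      f"down {p.sigma - ac / p.delta:.3f}")

for alpha in (-0.6, 0.0, 0.6):
    roots = ", ".join(
        f"{r.x:+.3f}{'(s)' if r.stable else '(u)'}"
        for r in fixed_points(alpha).roots
    )
    print(f"fixed points at alpha={alpha:+.1f}: {roots}")

up, down = hysteresis_loop(0.5, 1.1, n=1201, p=p)
print(f"swept transitions      : ascending {up:.4f}, descending {down:.4f}")
print(f"hysteresis loop width  : {up - down:.4f} E/A "
      f"(analytic 2*alpha_c/delta = {2 * ac / p.delta:.4f})")
# Ascending sweeps keep not-passing up to a higher E/A than descending
# sweeps keep passing: the signature of bistability.
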