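"""Naive one-sample-at-a-time reference implementation of the window
features, used as the oracle for the vectorized computation.

Deliberately written with plain Python loops and the ``statistics``
module where possible, sharing no code with the package implementation.
"""

from __future__ import annotations

import math


def _mean(v):
    return sum(v) / len(v)


def _sd_n(v):
    m = _mean(v)
    return math.sqrt(sum((x - m) ** 2 for x in v) / len(v))


def _percentile_linear(v, q):
    s = sorted(v)
    pos = (len(s) - 1) * q / 100.0
    lo = math.floor(pos)
    hi = math.ceil(pos)
    if lo == hi:
        return s[lo]
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


def _crossings(seq):
    count = 0
    prev_sign = 0
    for value in seq:
        sign = (value > 0) - (value < 0)
        if sign == 0:
            sign = prev_sign
        if prev_sign != 0 and sign != 0 and sign != prev_sign:
            count += 1
        if sign != 0:
            prev_sign = sign
    return count


def reference_features(window):
    """All 41 features of an (n, 3) window, keyed by feature name."""
    n = len(window)
    axes = {"x": [r[0] for r in window], "y": [r[1] for r in window], "z": [r[2] for r in window]}
    out = {}
    for a, v in axes.items():
        out[f"mean_{a}"] = _mean(v)
    for a, v in axes.items():
        out[f"sd_{a}"] = _sd_n(v)
    for a, v in axes.items():
        out[f"max_{a}"] = max(v)
    for a, v in axes.items():
        out[f"min_{a}"] = min(v)
    out["mean_vecnorm"] = _mean(
        [math.sqrt(r[0] ** 2 + r[1] ** 2 + r[2] ** 2) for r in window]
    )
    dba = {a: [x - out[f"mean_{a}"] for x in v] for a, v in axes.items()}
    for pa, pb in (("x", "y"), ("x", "z"), ("y", "z")):
        cov = sum(da * db for da, db in zip(dba[pa], dba[pb])) / n
        out[f"cov_{pa}{pb}"] = cov
    for pa, pb in (("x", "y"), ("x", "z"), ("y", "z")):
        sa, sb = out[f"sd_{pa}"], out[f"sd_{pb}"]
        out[f"corr_{pa}{pb}"] = (
            out[f"cov_{pa}{pb}"] / (sa * sb) if sa > 0 and sb > 0 else 0.0
        )
    for a in axes:
        out[f"mean_dba_{a}"] = _mean([abs(d) for d in dba[a]])
    out["odba"] = _mean(
        [abs(dx) + abs(dy) + abs(dz) for dx, dy, dz in zip(dba["x"], dba["y"], dba["z"])]
    )
    for a, v in axes.items():
        diffs = [v[i + 1] - v[i] for i in range(n - 1)]
        out[f"mean_diff_{a}"] = _mean([abs(d) for d in diffs])
        out[f"std_diff_{a}"] = _sd_n(diffs)
    for a, v in axes.items():
        out[f"wave_amp_{a}"] = max(v) - min(v)
    for a in axes:
        out[f"crossings_{a}"] = _crossings(dba[a])
    for q in (25, 50, 75):
        for a, v in axes.items():
            out[f"p{q}_{a}"] = _percentile_linear(v, q)
    return out
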