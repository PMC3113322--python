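"""Independent brute-force reference implementations used to cross-check
the vectorized peak-search primitives."""

import numpy as np


def brute_force_p1(values, fs, t0, start_s, a1):
    """Exhaustive scan: first sample at/after start_s that is rising and > a1."""
    for i in range(1, len(values)):
        t = t0 + i / fs
        if t < start_s - 1e-12:
            continue
        if values[i] > a1 and values[i] > values[i - 1]:
            return t
    return None


def brute_force_local_max(values, fs, t0, from_s):
    """Exhaustive scan: first interior sample with v[i-1] < v[i] >= v[i+1]."""
    for i in range(1, len(values) - 1):
        t = t0 + i / fs
        if t < from_s - 1e-12:
            continue
        if values[i - 1] < values[i] >= values[i + 1]:
            return t
    return None


def random_test_signal(rng, n=None):
    """A smooth-ish random signal with a few bumps plus noise."""
    n = n or int(rng.integers(50, 400))
    t = np.linspace(0, 1, n)
    x = np.zeros(n)
    for _ in range(rng.integers(1, 5)):
        c = rng.uniform(0.1, 0.9)
        w = rng.uniform(0.02, 0.2)
        x += rng.uniform(-1, 1) * np.exp(-0.5 * ((t - c) / w) ** 2)
    x += rng.normal(0, 0.05, n)
    return x
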