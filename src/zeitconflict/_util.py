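"""Shared helpers: circular arithmetic on the 24-h clock and seeding."""

from __future__ import annotations

import numpy as np

HOURS_PER_DAY = 24.0


def hours_to_radians(hours, period: float = HOURS_PER_DAY):
    return np.asarray(hours, dtype=float) * 2.0 * np.pi / period


def radians_to_hours(rad, period: float = HOURS_PER_DAY):
    return (np.asarray(rad, dtype=float) * period / (2.0 * np.pi)) % period


def wrap_signed_hours(delta, period: float = HOURS_PER_DAY):
    """Wrap an hour difference to the signed half-open interval (-period/2, period/2]."""
    d = np.asarray(delta, dtype=float)
    out = -((-d + period / 2.0) % period - period / 2.0)
    # map -period/2 -> +period/2 so the interval is (-p/2, p/2]
    out = np.where(out == -period / 2.0, period / 2.0, out)
    return out if out.ndim else float(out)


def circular_distance_hours(a, b, period: float = HOURS_PER_DAY):
    """Unsigned circular distance in hours, in [0, period/2]."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    d = np.minimum(d, period - d)
    return d if d.ndim else float(d)


def check_seed(seed) -> int:
    seed = int(seed)
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    return seed


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic independent generators derived from one root seed."""
    ss = np.random.SeedSequence(check_seed(seed))
    return [np.random.default_rng(s) for s in ss.spawn(n)]
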