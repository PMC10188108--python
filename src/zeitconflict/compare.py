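"""Comparison of rhythms between groups and conditions.

Cosinor-based comparison of mesor/amplitude/acrophase (the decision
semantics of CircaCompare-style testing: a joint linear model in cos/sin
with group interaction terms, delta-method standard errors for amplitude
and phase), circular summaries and uniformity/homogeneity tests, phase
attribution to competing zeitgebers, and the half-period alignment
procedure for populations split into antiphase activity groups.

All public interfaces take and return hours on the 24-h zeitgeber clock;
radian conversion is internal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._util import (
    HOURS_PER_DAY,
    check_seed,
    circular_distance_hours,
    hours_to_radians,
    radians_to_hours,
    wrap_signed_hours,
)
from .rhythm import RhythmResult, lsp_permutation_test
from .tracks import ActivitySeries, GroupProfile, group_mean_profile

__all__ = [
    "CosinorFit",
    "CosinorComparison",
    "CircularSummary",
    "cosinor_fit",
    "cosinor_group_comparison",
    "circular_summary",
    "rayleigh_test",
    "watson_two_sample",
    "zeitgeber_phase_attribution",
    "align_half_period",
]


@dataclass
class CosinorFit:
    """y = M + A*cos(2*pi/tau * (t - phi)) fitted by linear least squares."""

    mesor: float
    amplitude: float
    acrophase_h: float
    period_h: float
    cov: np.ndarray  # covariance of (M, beta_cos, beta_sin)
    resid_var: float
    n: int
    degenerate: bool = False  # flat series: amplitude 0, phase reported as 0

    def predict(self, t):
        om = 2.0 * np.pi / self.period_h
        return self.mesor + self.amplitude * np.cos(om * (np.asarray(t) - self.acrophase_h))


@dataclass
class CosinorComparison:
    d_mesor: float
    d_amplitude: float
    d_phase_h: float  # signed circular difference group2 - group1, in (-tau/2, tau/2]
    p_mesor: float
    p_amplitude: float
    p_phase: float
    se_phase_h: float
    fit1: CosinorFit
    fit2: CosinorFit
    phase_undefined: bool = False


@dataclass
class CircularSummary:
    mean_direction_h: float
    resultant_length: float

    @property
    def circular_variance(self) -> float:
        return 1.0 - self.resultant_length


# ---------------------------------------------------------------------------
# cosinor
# ---------------------------------------------------------------------------

def _cosinor_design(t: np.ndarray, period: float) -> np.ndarray:
    om = 2.0 * np.pi / period
    return np.column_stack([np.ones_like(t), np.cos(om * t), np.sin(om * t)])


def cosinor_fit(t, y, period: float = 24.0) -> CosinorFit:
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 4:
        raise ValueError("need at least 4 observations")
    if len(np.unique(np.round(t % period, 9))) < 3:
        raise ValueError("need at least 3 distinct times mod period")
    X = _cosinor_design(t, period)
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("collinear cosinor design")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(1, len(y) - 3)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    amp = float(np.hypot(beta[1], beta[2]))
    if amp < 1e-12:
        return CosinorFit(float(beta[0]), 0.0, 0.0, period, cov, s2, len(y), degenerate=True)
    om = 2.0 * np.pi / period
    phi = float((np.arctan2(beta[2], beta[1]) / om) % period)
    return CosinorFit(float(beta[0]), amp, phi, period, cov, s2, len(y))


def cosinor_group_comparison(t1, y1, t2, y2, period: float = 24.0) -> CosinorComparison:
    """Wald tests for mesor, amplitude and acrophase differences.

    Joint model: y = M + dM*g + b_c*cos + b_s*sin + d_c*g*cos + d_s*g*sin,
    g the group-2 indicator. Amplitude and phase per group are smooth
    functions of the coefficients; their difference gets delta-method
    standard errors. The phase difference is wrapped to (-tau/2, tau/2].
    """
    t1 = np.asarray(t1, dtype=float); y1 = np.asarray(y1, dtype=float)
    t2 = np.asarray(t2, dtype=float); y2 = np.asarray(y2, dtype=float)
    fit1 = cosinor_fit(t1, y1, period)
    fit2 = cosinor_fit(t2, y2, period)
    t = np.concatenate([t1, t2])
    y = np.concatenate([y1, y2])
    g = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    om = 2.0 * np.pi / period
    X = np.column_stack([
        np.ones_like(t), g, np.cos(om * t), np.sin(om * t),
        g * np.cos(om * t), g * np.sin(om * t),
    ])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 6:
        raise ValueError("collinear joint cosinor design")
    resid = y - X @ beta
    dof = max(1, len(y) - 6)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)

    c1, s1 = beta[2], beta[3]
    c2, s2b = beta[2] + beta[4], beta[3] + beta[5]
    A1 = np.hypot(c1, s1)
    A2 = np.hypot(c2, s2b)
    undefined = A1 < 1e-12 or A2 < 1e-12

    # mesor difference: plain coefficient test
    se_m = np.sqrt(cov[1, 1])
    z_m = beta[1] / se_m if se_m > 0 else 0.0
    p_mesor = 2.0 * stats.t.sf(abs(z_m), dof)

    # amplitude difference: dA = A2 - A1
    gA = np.zeros(6)
    if not undefined:
        gA[2] = c2 / A2 - c1 / A1
        gA[3] = s2b / A2 - s1 / A1
        gA[4] = c2 / A2
        gA[5] = s2b / A2
    var_A = float(gA @ cov @ gA)
    dA = float(A2 - A1)
    p_amp = (2.0 * stats.t.sf(abs(dA) / np.sqrt(var_A), dof)
             if var_A > 0 else float("nan"))

    # phase difference: dpsi = atan2(s2, c2) - atan2(s1, c1), wrapped
    if undefined:
        d_phi = float("nan"); p_phase = float("nan"); se_phi = float("nan")
    else:
        psi1 = np.arctan2(s1, c1)
        psi2 = np.arctan2(s2b, c2)
        d_phi = wrap_signed_hours((psi2 - psi1) / om, period)
        gP = np.zeros(6)
        gP[2] = -s2b / A2 ** 2 + s1 / A1 ** 2
        gP[3] = c2 / A2 ** 2 - c1 / A1 ** 2
        gP[4] = -s2b / A2 ** 2
        gP[5] = c2 / A2 ** 2
        var_psi = float(gP @ cov @ gP)
        se_phi = np.sqrt(var_psi) / om  # hours
        z = abs(d_phi) / se_phi if se_phi > 0 else np.inf
        p_phase = 2.0 * stats.t.sf(z, dof)

    return CosinorComparison(
        d_mesor=float(beta[1]), d_amplitude=dA, d_phase_h=float(d_phi),
        p_mesor=float(p_mesor), p_amplitude=float(p_amp), p_phase=float(p_phase),
        se_phase_h=float(se_phi), fit1=fit1, fit2=fit2, phase_undefined=undefined,
    )


# ---------------------------------------------------------------------------
# circular statistics
# ---------------------------------------------------------------------------

def circular_summary(phases_h, period: float = HOURS_PER_DAY) -> CircularSummary:
    ph = np.asarray(phases_h, dtype=float)
    if len(ph) < 1:
        raise ValueError("need at least one phase")
    ang = hours_to_radians(ph, period)
    C = np.cos(ang).mean()
    S = np.sin(ang).mean()
    R = float(np.hypot(C, S))
    mean_h = float(radians_to_hours(np.arctan2(S, C), period)) if R > 1e-15 else float("nan")
    return CircularSummary(mean_direction_h=mean_h, resultant_length=R)


def rayleigh_test(phases_h, period: float = HOURS_PER_DAY,
                  monte_carlo: bool = False, n_mc: int = 100_000,
                  seed: int = 0) -> float:
    """Rayleigh test of circular uniformity; returns the p-value.

    Uses the finite-n corrected approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)); for very small
    samples a Monte-Carlo null on the resultant length is available.
    """
    ph = np.asarray(phases_h, dtype=float)
    n = len(ph)
    if n < 3:
        raise ValueError("need at least 3 phases")
    R = circular_summary(ph, period).resultant_length
    if monte_carlo:
        rng = np.random.default_rng(check_seed(seed))
        ang = rng.uniform(0, 2 * np.pi, (n_mc, n))
        Rnull = np.hypot(np.cos(ang).mean(axis=1), np.sin(ang).mean(axis=1))
        return float((1 + np.sum(Rnull >= R)) / (n_mc + 1))
    Rn = n * R
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - Rn * Rn)) - (1.0 + 2.0 * n))
    return float(min(1.0, p))


def _watson_u2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Watson two-sample U^2 on circular data, batched over leading axes."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    n, m = a.shape[-1], b.shape[-1]
    N = n + m
    pooled = np.concatenate([a, b], axis=-1)
    is_a = np.zeros(N)
    is_a[:n] = 1.0
    order = np.argsort(pooled, axis=-1, kind="stable")
    ind = is_a[order] if order.ndim == 1 else is_a[order]
    cum_a = np.cumsum(ind, axis=-1) / n
    cum_b = np.cumsum(1.0 - ind, axis=-1) / m
    d = cum_a - cum_b
    return (n * m / N ** 2) * (np.sum(d * d, axis=-1) - np.sum(d, axis=-1) ** 2 / N)


def watson_two_sample(phases1_h, phases2_h, n_boot: int = 9999, seed: int = 0,
                      period: float = HOURS_PER_DAY):
    """Bootstrapped Watson U^2 test for a common phase distribution.

    The null resamples both groups (with replacement) from the pooled
    sample; p = (1 + #{U2* >= U2}) / (n_boot + 1).

    Returns (u2, p).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    a = np.asarray(phases1_h, dtype=float) % period
    b = np.asarray(phases2_h, dtype=float) % period
    if len(a) < 4 or len(b) < 4:
        raise ValueError("both samples need n >= 4")
    u2 = float(_watson_u2(a, b)[0])
    if u2 <= 0:
        return 0.0, 1.0
    rng = np.random.default_rng(check_seed(seed))
    pooled = np.concatenate([a, b])
    ia = rng.integers(0, len(pooled), (n_boot, len(a)))
    ib = rng.integers(0, len(pooled), (n_boot, len(b)))
    u2_null = _watson_u2(pooled[ia], pooled[ib])
    p = (1.0 + np.sum(u2_null >= u2)) / (n_boot + 1.0)
    return u2, float(p)


def circular_homogeneity_test(phases1_h, phases2_h, n_mc: int = 10_000,
                              seed: int = 0, period: float = HOURS_PER_DAY):
    """Monte-Carlo two-sample test that two phase samples share one distribution.

    Statistic: T = sum_j n_j * ||mean_vector_j - pooled_mean_vector||^2,
    sensitive to differences in both mean direction and concentration; the
    null permutes group labels (``n_mc`` replications).

    Returns (statistic, p).
    """
    a = hours_to_radians(np.asarray(phases1_h, dtype=float), period)
    b = hours_to_radians(np.asarray(phases2_h, dtype=float), period)
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)

    def _stat(x1, x2):
        v1 = np.array([np.cos(x1).mean(axis=-1), np.sin(x1).mean(axis=-1)])
        v2 = np.array([np.cos(x2).mean(axis=-1), np.sin(x2).mean(axis=-1)])
        vp = (n1 * v1 + n2 * v2) / (n1 + n2)
        return n1 * np.sum((v1 - vp) ** 2, axis=0) + n2 * np.sum((v2 - vp) ** 2, axis=0)

    T = float(_stat(a, b))
    rng = np.random.default_rng(check_seed(seed))
    idx = np.argsort(rng.random((n_mc, n1 + n2)), axis=1)
    perm = pooled[idx]
    Tnull = _stat(perm[:, :n1], perm[:, n1:])
    p = (1.0 + np.sum(Tnull >= T)) / (n_mc + 1.0)
    return T, float(p)


# ---------------------------------------------------------------------------
# zeitgeber phase attribution
# ---------------------------------------------------------------------------

def zeitgeber_phase_attribution(phases_h, offset_h: float,
                                expected_light_h: float = 18.0,
                                alpha: float = 0.05):
    """Which zeitgeber does each individual's phase track?

    Expected phase of a light-entrained rhythm is ``expected_light_h``
    (peak activity at ZT18 on the lights-on clock); a temperature-entrained
    rhythm is expected ``offset_h`` later. Per individual the circular
    distances to both expectations are compared with a paired Wilcoxon
    signed-rank test.

    Returns dict with d_light, d_temp arrays, p, and a verdict in
    {'light-closer', 'temp-closer', 'equidistant'}.
    """
    ph = np.asarray(phases_h, dtype=float)
    if len(ph) == 0:
        raise ValueError("empty phase sample")
    exp_temp = (expected_light_h + offset_h) % HOURS_PER_DAY
    d_light = circular_distance_hours(ph, expected_light_h)
    d_temp = circular_distance_hours(ph, exp_temp)
    diff = np.atleast_1d(d_light - d_temp)
    if np.allclose(diff, 0.0):
        p = 1.0
    else:
        mode = "exact" if len(diff) <= 25 else "approx"
        p = float(stats.wilcoxon(diff, mode=mode, correction=(mode == "approx")).pvalue)
    if p >= alpha:
        verdict = "equidistant"
    else:
        verdict = "light-closer" if np.median(diff) < 0 else "temp-closer"
    return {
        "d_light": np.atleast_1d(d_light),
        "d_temp": np.atleast_1d(d_temp),
        "p": p,
        "verdict": verdict,
        "expected_light_h": expected_light_h,
        "expected_temp_h": exp_temp,
    }


# ---------------------------------------------------------------------------
# half-period alignment
# ---------------------------------------------------------------------------

def align_half_period(series: list[ActivitySeries], window_h: float = 12.0,
                      period_lo: float = 20.0, period_hi: float = 28.0,
                      n_perm: int = 2000, seed: int = 0):
    """Align antiphase sub-populations before testing the mean for rhythm.

    Each animal is assigned to the half-day window ([0,12) or [12,24) ZT,
    hours taken mod 24) holding the larger share of its total activity;
    the second group's series are shifted by 12 h, the group mean profile
    is recomputed and Lomb-Scargle tested. Ties in window totals go to
    [0,12) deterministically and are flagged.

    Returns (GroupProfile, RhythmResult, assignment DataFrame).
    """
    import pandas as pd

    if not series:
        raise ValueError("no series to align")
    grid = series[0].zt_hours
    if np.ptp(grid) + 1 < 48:
        raise ValueError("series must cover at least 48 h")
    shift_bins = int(round(window_h))
    records = []
    aligned = []
    for s in series:
        if len(s.zt_hours) != len(grid) or np.any(s.zt_hours != grid):
            raise ValueError("series are not on a common ZT grid")
        hmod = s.zt_hours % 24
        tot_early = s.norm_distance[hmod < window_h].sum()
        tot_late = s.norm_distance[hmod >= window_h].sum()
        tie = np.isclose(tot_early, tot_late)
        win = 0 if (tie or tot_early > tot_late) else 1
        vals = np.roll(s.norm_distance, shift_bins) if win == 1 else s.norm_distance
        aligned.append(
            ActivitySeries(
                animal_id=s.animal_id, zt_hours=grid,
                distance_cm=np.roll(s.distance_cm, shift_bins) if win == 1 else s.distance_cm,
                pct_active=np.roll(s.pct_active, shift_bins) if win == 1 else s.pct_active,
                norm_distance=vals, inactive=s.inactive,
            )
        )
        records.append({"animal_id": s.animal_id, "window": win, "tie": bool(tie)})
    profile = group_mean_profile(aligned, group="aligned")
    result = lsp_permutation_test(
        profile.zt_hours.astype(float), profile.mean,
        period_lo=period_lo, period_hi=period_hi, n_perm=n_perm, seed=seed,
    )
    return profile, result, pd.DataFrame(records)
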