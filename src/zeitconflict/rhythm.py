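"""Rhythmicity detection.

Four complementary tests, spanning the behavior and expression arms of the
pipeline:

* ``lsp_permutation_test`` — classical variance-normalized Lomb-Scargle
  periodogram restricted to a period band (default 20-28 h; 10-14 h for
  circatidal screens), significance by shuffling values across time points.
* ``lsp_replicate_permutation_test`` — the replicate-aware variant used for
  qPCR-style designs: all individual replicate values are shuffled jointly
  and per-timepoint means recomputed before each null periodogram.
* ``empirical_jtk_24h`` — a permutation-calibrated reference-waveform test:
  the statistic is the maximum Kendall tau between the series and a bank of
  24-h cosines at hourly phases, so it tests for 24-h periods specifically.
* ``umbrella_rhythm_test`` — a nonparametric screen for possibly asymmetric
  24-h waveforms: for every candidate peak time and rise length (in 4-h
  increments) a Mack-Wolfe-type umbrella statistic (Jonckheere-Terpstra
  pair counts along the rising and falling arms, with periodic closure of
  the trough) is calibrated against a design-level Monte-Carlo permutation
  null, and the minimum p over shapes is Bonferroni-corrected by the
  number of shapes.
* ``mfourfit_estimate`` — truncated-Fourier curve fitting on a fine period
  grid for accurate period/phase/amplitude estimation on short series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import lombscargle

from ._util import check_seed

__all__ = [
    "RhythmResult",
    "ReplicatedSeries",
    "lsp_power",
    "lsp_permutation_test",
    "lsp_replicate_permutation_test",
    "empirical_jtk_24h",
    "mfourfit_estimate",
    "umbrella_rhythm_test",
]


@dataclass
class RhythmResult:
    method: str
    p_raw: float
    statistic: float
    period_h: float
    phase_h: float = float("nan")
    amplitude: float = float("nan")
    p_adj: float = float("nan")
    n_perm: int = 0
    extra: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> bool:
        p = self.p_adj if adjusted and np.isfinite(self.p_adj) else self.p_raw
        return p < alpha


@dataclass
class ReplicatedSeries:
    """Time series with replicate measurements per time point (ragged allowed)."""

    timepoints: np.ndarray
    values: list  # one 1-D array per timepoint

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.values = [np.atleast_1d(np.asarray(v, dtype=float)) for v in self.values]
        if len(self.timepoints) != len(self.values):
            raise ValueError("one value array per timepoint required")
        if len(self.timepoints) < 3:
            raise ValueError("need at least 3 distinct timepoints")
        if any(len(v) < 1 for v in self.values):
            raise ValueError("each timepoint needs at least one replicate")

    @property
    def mean_series(self) -> np.ndarray:
        return np.array([v.mean() for v in self.values])

    @property
    def n_values(self) -> int:
        return int(sum(len(v) for v in self.values))


# ---------------------------------------------------------------------------
# Lomb-Scargle
# ---------------------------------------------------------------------------

def default_period_grid(period_lo: float, period_hi: float, step: float = 0.1) -> np.ndarray:
    return np.arange(period_lo, period_hi + step / 2.0, step)


def lsp_power(t, y, periods):
    """Variance-normalized Lomb-Scargle power on a period grid.

    Power is the fraction of series variance explained at each period
    (a noise-free sinusoid at a grid period scores 1). A constant series
    has zero power everywhere.

    Returns (powers, peak_period, peak_power).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    periods = np.asarray(periods, dtype=float)
    if len(t) < 2 or len(t) != len(y):
        raise ValueError("need matched t and y with at least 2 points")
    if np.any(periods <= 0):
        raise ValueError("periods must be positive")
    if np.ptp(y) == 0:
        powers = np.zeros(len(periods))
    else:
        powers = lombscargle(t, y - y.mean(), 2.0 * np.pi / periods, normalize=True)
    k = int(np.argmax(powers))
    return powers, float(periods[k]), float(powers[k])


def _ls_basis(t: np.ndarray, periods: np.ndarray):
    """Precompute tau-shifted cosine/sine bases for fixed sampling times.

    Enables one-matmul evaluation of the normalized periodogram for many
    series sharing the same time points (the permutation null).
    """
    omegas = 2.0 * np.pi / periods
    C = np.empty((len(periods), len(t)))
    S = np.empty_like(C)
    for k, om in enumerate(omegas):
        tau = np.arctan2(np.sum(np.sin(2 * om * t)), np.sum(np.cos(2 * om * t))) / (2 * om)
        C[k] = np.cos(om * (t - tau))
        S[k] = np.sin(om * (t - tau))
    cc = (C * C).sum(axis=1)
    ss = (S * S).sum(axis=1)
    return C, S, cc, ss


def _ls_peak_power_many(C, S, cc, ss, Y: np.ndarray) -> np.ndarray:
    """Peak normalized LS power for each column of Y (n_obs x n_series)."""
    Yc = Y - Y.mean(axis=0, keepdims=True)
    denom = (Yc * Yc).sum(axis=0)
    denom = np.where(denom == 0, np.inf, denom)
    power = ((C @ Yc) ** 2 / cc[:, None] + (S @ Yc) ** 2 / ss[:, None]) / denom[None, :]
    return power.max(axis=0)


def _perm_matrix(rng, y: np.ndarray, n_perm: int) -> np.ndarray:
    idx = np.argsort(rng.random((n_perm, len(y))), axis=1)
    return y[idx].T  # n_obs x n_perm


def lsp_permutation_test(t, y, period_lo: float = 20.0, period_hi: float = 28.0,
                         n_perm: int = 2000, seed: int = 0,
                         grid_step: float = 0.1) -> RhythmResult:
    """Lomb-Scargle rhythm test with a shuffle-across-timepoints null.

    p = (1 + #{null peak power >= observed}) / (n_perm + 1); the smallest
    attainable p is therefore 1/(n_perm+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 8:
        raise ValueError("need at least 8 observations")
    periods = default_period_grid(period_lo, period_hi, grid_step)
    powers, peak_period, peak_power = lsp_power(t, y, periods)
    rng = np.random.default_rng(check_seed(seed))
    C, S, cc, ss = _ls_basis(t, periods)
    null_peaks = _ls_peak_power_many(C, S, cc, ss, _perm_matrix(rng, y, n_perm))
    p = (1.0 + np.sum(null_peaks >= peak_power)) / (n_perm + 1.0)
    phase, amp = _cosinor_phase_amplitude(t, y, peak_period)
    return RhythmResult(
        method="lsp_perm", p_raw=float(p), statistic=peak_power,
        period_h=peak_period, phase_h=phase, amplitude=amp, n_perm=n_perm,
    )


def lsp_replicate_permutation_test(rep: ReplicatedSeries, period_lo: float = 20.0,
                                   period_hi: float = 28.0, n_perm: int = 2000,
                                   seed: int = 0, grid_step: float = 0.1) -> RhythmResult:
    """Replicate-aware Lomb-Scargle permutation test.

    The observed statistic is the peak power of the per-timepoint mean
    series; the null shuffles *all* replicate values jointly, re-computes
    the timepoint means, and re-runs the periodogram. With one replicate
    per timepoint this reduces exactly to ``lsp_permutation_test``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t = rep.timepoints
    flat = np.concatenate(rep.values)
    sizes = np.array([len(v) for v in rep.values])
    # averaging operator: timepoints x values
    A = np.zeros((len(t), len(flat)))
    pos = 0
    for i, s in enumerate(sizes):
        A[i, pos:pos + s] = 1.0 / s
        pos += s
    mean_series = A @ flat
    periods = default_period_grid(period_lo, period_hi, grid_step)
    _, peak_period, peak_power = lsp_power(t, mean_series, periods)
    rng = np.random.default_rng(check_seed(seed))
    C, S, cc, ss = _ls_basis(t, periods)
    null_means = A @ _perm_matrix(rng, flat, n_perm)
    null_peaks = _ls_peak_power_many(C, S, cc, ss, null_means)
    p = (1.0 + np.sum(null_peaks >= peak_power)) / (n_perm + 1.0)
    phase, amp = _cosinor_phase_amplitude(t, mean_series, peak_period)
    return RhythmResult(
        method="lsp_perm_replicate", p_raw=float(p), statistic=peak_power,
        period_h=peak_period, phase_h=phase, amplitude=amp, n_perm=n_perm,
        extra={"n_values": rep.n_values},
    )


def _cosinor_phase_amplitude(t, y, period):
    om = 2.0 * np.pi / period
    X = np.column_stack([np.ones_like(t), np.cos(om * t), np.sin(om * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    amp = float(np.hypot(beta[1], beta[2]))
    if amp == 0:
        return 0.0, 0.0
    phase = (np.arctan2(beta[2], beta[1]) / om) % period
    return float(phase), amp


# ---------------------------------------------------------------------------
# empirical JTK (24-h reference-waveform test)
# ---------------------------------------------------------------------------

def _pair_signs(v: np.ndarray) -> np.ndarray:
    """Signs of all i<j pair differences, flattened (basis of Kendall tau).

    Differences below a relative tolerance count as ties, so periodic
    repeats of a noise-free waveform compare as exactly tied.
    """
    n = v.shape[-1]
    iu = np.triu_indices(n, k=1)
    diff = v[..., iu[1]] - v[..., iu[0]]
    tol = 1e-9 * max(1.0, float(np.max(np.abs(v))))
    s = np.sign(diff)
    s[np.abs(diff) <= tol] = 0.0
    return s


def empirical_jtk_24h(t, y, n_phase_refs: int = 24, n_perm: int = 1000,
                      seed: int = 0, period: float = 24.0) -> RhythmResult:
    """Max Kendall-tau agreement with 24-h reference cosines, permutation p.

    The statistic is the maximum Kendall tau-b between the series and
    reference cosines peaking at ``n_phase_refs`` evenly spaced phases; a
    noise-free 24-h cosine therefore scores tau = 1 at its own phase. The
    null permutes the series against the fixed reference bank.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < 12:
        raise ValueError("need at least 12 observations")
    phases = np.arange(n_phase_refs) * (period / n_phase_refs)
    refs = np.cos(2.0 * np.pi / period * (t[None, :] - phases[:, None]))
    s_ref = _pair_signs(refs)  # n_refs x n_pairs
    s_y = _pair_signs(y[None, :])[0]
    n_pairs = s_y.shape[0]
    t_ref = (s_ref == 0).sum(axis=1)
    t_y = (s_y == 0).sum()
    denom = np.sqrt((n_pairs - t_ref) * (n_pairs - t_y))
    denom = np.where(denom == 0, np.inf, denom)

    taus = (s_ref @ s_y) / denom
    best = int(np.argmax(taus))
    stat = float(taus[best])

    rng = np.random.default_rng(check_seed(seed))
    perm = _perm_matrix(rng, y, n_perm).T  # n_perm x n_obs
    s_perm = _pair_signs(perm)  # n_perm x n_pairs
    null_taus = (s_perm @ s_ref.T) / denom[None, :]
    null_stat = null_taus.max(axis=1)
    p = (1.0 + np.sum(null_stat >= stat)) / (n_perm + 1.0)
    return RhythmResult(
        method="ejtk", p_raw=float(p), statistic=stat, period_h=period,
        phase_h=float(phases[best]), n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# multi-harmonic period/phase estimation
# ---------------------------------------------------------------------------

def mfourfit_estimate(t, y, period_lo: float = 20.0, period_hi: float = 28.0,
                      n_harmonics: int = 3, grid_step: float = 0.02) -> RhythmResult:
    """Truncated-Fourier curve fitting over a fine period grid.

    For each candidate period the series is least-squares fitted with a
    fundamental plus up to ``n_harmonics - 1`` overtones; the number of
    harmonics is selected by BIC so that noisy sinusoids are not overfit
    while structured (e.g. sawtooth-like) waveforms keep their overtones.
    The (period, harmonic-count) pair minimizing BIC wins; ties break to
    the smaller period. Phase is the argmax of the fitted waveform over
    one period; amplitude is half its peak-to-trough range.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_par = 2 * n_harmonics + 1
    if n < 2 * n_par:
        raise ValueError(f"need at least {2 * n_par} observations")
    span = np.ptp(t)
    if not (0 < period_lo <= period_hi <= 2 * span):
        raise ValueError("period range must lie in (0, 2*span]")
    periods = np.arange(period_lo, period_hi + grid_step / 2.0, grid_step)
    best = None  # (bic, tau, beta, h)
    for tau in periods:
        om = 2.0 * np.pi / tau
        cols = [np.ones_like(t)]
        for k in range(1, n_harmonics + 1):
            cols += [np.cos(k * om * t), np.sin(k * om * t)]
        X = np.column_stack(cols)
        for h in range(1, n_harmonics + 1):
            Xh = X[:, : 2 * h + 1]
            beta, *_ = np.linalg.lstsq(Xh, y, rcond=None)
            rss = float(np.sum((y - Xh @ beta) ** 2))
            k_par = 2 * h + 2  # coefficients + period
            bic = n * np.log(max(rss, 1e-300) / n) + k_par * np.log(n)
            if best is None or bic < best[0] - 1e-10:
                best = (bic, tau, beta, h)
    _, tau, beta, h = best
    tt = np.arange(0.0, tau, 0.01)
    om = 2.0 * np.pi / tau
    wave = np.full_like(tt, beta[0])
    for k in range(1, h + 1):
        wave += beta[2 * k - 1] * np.cos(k * om * tt) + beta[2 * k] * np.sin(k * om * tt)
    phase = float(tt[np.argmax(wave)])
    amp = float((wave.max() - wave.min()) / 2.0)
    coef = np.zeros(n_par)
    coef[: len(beta)] = beta
    rss = float(np.sum((y - np.column_stack(
        [np.ones_like(t)] + [f(k * om * t) for k in range(1, h + 1)
                             for f in (np.cos, np.sin)]) @ beta) ** 2))
    return RhythmResult(
        method="mfourfit", p_raw=float("nan"), statistic=rss, period_h=float(tau),
        phase_h=phase, amplitude=amp,
        extra={"coefficients": coef, "n_harmonics_used": h},
    )


# ---------------------------------------------------------------------------
# umbrella (asymmetric-waveform) screen
# ---------------------------------------------------------------------------

def umbrella_shapes(group_times: np.ndarray, period: float = 24.0,
                    asym_step_h: float = 4.0,
                    peak_border: tuple = (0.3, 0.7)) -> list:
    """Enumerate unique periodic umbrella shapes as directed group-pair sets.

    Candidate peaks are the sampled times mod period; rise lengths run in
    ``asym_step_h`` increments across the ``peak_border`` fraction of the
    period (default 0.3-0.7, i.e. rises of 8-16 h on a 24-h clock: extreme
    sawtooth shapes are excluded, as is conventional for umbrella rhythm
    screens). A
    shape implies value(a) < value(b) for every pair ordered along the
    rising arm, every pair ordered along the falling arm, and — because
    the waveform is periodic so the trough is a global minimum — for the
    trough against every falling-arm group. Each shape carries the list of
    implied directed pairs ``pairs`` (a, b meaning group a below group b).
    """
    gt = np.asarray(group_times, dtype=float)
    seen = {}
    rises = np.arange(asym_step_h, period - asym_step_h / 2.0, asym_step_h)
    lo, hi = peak_border
    rises = rises[(rises >= lo * period - 1e-9) & (rises <= hi * period + 1e-9)]
    for peak in gt:
        for r in rises:
            trough = (peak - r) % period
            q = (gt - trough) % period
            rising = np.flatnonzero(q <= r + 1e-9)
            falling = np.flatnonzero(q > r + 1e-9)
            rise_order = rising[np.argsort(q[rising])]
            fall_order = falling[np.argsort(q[falling])]  # descending levels
            pairs = set()
            for i in range(len(rise_order)):
                for j in range(i + 1, len(rise_order)):
                    pairs.add((int(rise_order[i]), int(rise_order[j])))
            peak_g = int(rise_order[-1])
            fall_chain = [peak_g] + [int(g) for g in fall_order]
            for i in range(len(fall_chain)):
                for j in range(i + 1, len(fall_chain)):
                    pairs.add((fall_chain[j], fall_chain[i]))
            # periodic closure: the trough sits below the falling arm too
            trough_g = int(rise_order[0]) if abs(q[rise_order[0]]) < 1e-9 else None
            if trough_g is not None:
                for g in fall_order:
                    pairs.add((trough_g, int(g)))
            key = frozenset(pairs)
            if key not in seen:
                seen[key] = {"peak_time": float(peak), "rise_h": float(r),
                             "pairs": sorted(pairs), "peak_group": peak_g}
    return list(seen.values())


def _pair_u_counts(V: np.ndarray, members: list) -> np.ndarray:
    """U[g, a, b] = #{x in group a < y in group b} + 0.5 ties, per series g."""
    G = V.shape[0]
    n_groups = len(members)
    U = np.zeros((G, n_groups, n_groups))
    for a in range(n_groups):
        for b in range(n_groups):
            if a == b:
                continue
            va = V[:, members[a]][:, :, None]
            vb = V[:, members[b]][:, None, :]
            U[:, a, b] = (va < vb).sum(axis=(1, 2)) + 0.5 * (va == vb).sum(axis=(1, 2))
    return U


def _shape_stats_from_u(U: np.ndarray, shapes: list) -> np.ndarray:
    """Per-series umbrella statistic for every shape, from pairwise U counts."""
    G = U.shape[0]
    out = np.empty((G, len(shapes)))
    for s, shape in enumerate(shapes):
        stat = np.zeros(G)
        for a, b in shape["pairs"]:
            stat += U[:, a, b]
        out[:, s] = stat
    return out


_NULL_CACHE: dict = {}


def _umbrella_null(sizes: tuple, shapes_key: tuple, shapes: list,
                   n_null: int, null_seed: int):
    """Sorted Monte-Carlo null statistics per shape for one sampling design.

    The null permutes the pooled observations, which for continuous data
    depends only on the group sizes and the shape pair sets — so one table
    serves every series sharing the design. Cached per design.
    """
    key = (sizes, shapes_key, n_null, null_seed)
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]
    rng = np.random.default_rng(check_seed(null_seed))
    N = int(sum(sizes))
    members = []
    pos = 0
    for s in sizes:
        members.append(np.arange(pos, pos + s))
        pos += s
    # weight matrix per shape at observation level, flattened
    W = np.zeros((len(shapes), N, N), dtype=np.float32)
    for si, shape in enumerate(shapes):
        for a, b in shape["pairs"]:
            W[si][np.ix_(members[a], members[b])] = 1.0
    Wf = W.reshape(len(shapes), -1).T
    chunk = max(1, min(n_null, 4000))
    stats_null = np.empty((n_null, len(shapes)), dtype=np.float32)
    done = 0
    while done < n_null:
        m = min(chunk, n_null - done)
        V = rng.random((m, N))
        C = (V[:, :, None] < V[:, None, :]).reshape(m, -1).astype(np.float32)
        stats_null[done:done + m] = C @ Wf
        done += m
    stats_null = np.sort(stats_null, axis=0)
    mean = stats_null.mean(axis=0)
    sd = stats_null.std(axis=0)
    _NULL_CACHE[key] = (stats_null, mean, sd)
    return _NULL_CACHE[key]


def umbrella_screen_matrix(values: np.ndarray, group_index: np.ndarray,
                           group_times: np.ndarray, period: float = 24.0,
                           asym_step_h: float = 4.0, n_null: int = 100_000,
                           null_seed: int = 171_717,
                           peak_border: tuple = (0.3, 0.7)):
    """Vectorized umbrella screen over many series sharing one design.

    Per-shape significance comes from a Monte-Carlo permutation null
    (``n_null`` pooled permutations, computed once per design and cached);
    p_raw is the minimum over shapes and p_adj the Bonferroni correction
    by the number of shapes. Ties are handled by the half-count convention
    in the statistic; the null is simulated from continuous draws, so
    heavily tied data will be tested conservatively.

    Parameters
    ----------
    values : (n_series, n_obs) matrix
    group_index : (n_obs,) int array mapping observations to time groups
    group_times : (n_groups,) times mod ``period`` of the groups

    Returns
    -------
    p_raw, p_adj, z_best, phase_best : arrays of length n_series
    n_shapes : int
    """
    V = np.atleast_2d(np.asarray(values, dtype=float))
    group_index = np.asarray(group_index)
    gt = np.asarray(group_times, dtype=float)
    n_groups = len(gt)
    if n_groups < 3:
        raise ValueError("need at least 3 distinct timepoints mod period")
    shapes = umbrella_shapes(gt, period, asym_step_h, peak_border)
    members = [np.flatnonzero(group_index == k) for k in range(n_groups)]
    sizes = tuple(len(m) for m in members)
    if min(sizes) < 1:
        raise ValueError("every timepoint group needs at least one observation")
    shapes_key = tuple(tuple(s["pairs"]) for s in shapes)

    U = _pair_u_counts(V, members)
    stat = _shape_stats_from_u(U, shapes)  # G x S

    null_sorted, null_mean, null_sd = _umbrella_null(
        sizes, shapes_key, shapes, n_null, null_seed
    )
    G, S = stat.shape
    p_shapes = np.empty((G, S))
    for s in range(S):
        idx = np.searchsorted(null_sorted[:, s], stat[:, s] - 1e-9, side="left")
        p_shapes[:, s] = (1.0 + (n_null - idx)) / (n_null + 1.0)
    zs = (stat - null_mean[None, :]) / np.where(null_sd > 0, null_sd, np.inf)[None, :]

    best = np.argmin(p_shapes + 1e-12 * -zs, axis=1)
    p_raw = p_shapes[np.arange(G), best]
    p_adj = np.minimum(1.0, p_raw * S)
    z_best = zs[np.arange(G), best]
    phase_best = np.array([shapes[b]["peak_time"] for b in best])
    return p_raw, p_adj, z_best, phase_best, S


def umbrella_rhythm_test(rep: ReplicatedSeries, period: float = 24.0,
                         asym_step_h: float = 4.0, n_null: int = 100_000,
                         null_seed: int = 171_717) -> RhythmResult:
    """Asymmetric-waveform rhythm test for one replicated series.

    Times are folded mod ``period`` (replicates pooled per folded time
    point); every candidate peak/rise-length umbrella shape is scored by
    the Mack-Wolfe statistic and the minimum p over shapes is Bonferroni
    adjusted by the number of shapes.
    """
    tmod = np.round(rep.timepoints % period, 9)
    uniq = np.unique(tmod)
    if len(uniq) < 3:
        raise ValueError("need at least 3 distinct timepoints mod period")
    flat = np.concatenate(rep.values)
    obs_groups = np.concatenate(
        [np.full(len(v), np.searchsorted(uniq, tm))
         for tm, v in zip(tmod, rep.values)]
    )
    p_raw, p_adj, z, phase, n_shapes = umbrella_screen_matrix(
        flat[None, :], obs_groups, uniq, period, asym_step_h,
        n_null=n_null, null_seed=null_seed,
    )
    return RhythmResult(
        method="umbrella", p_raw=float(p_raw[0]), p_adj=float(p_adj[0]),
        statistic=float(z[0]), period_h=period, phase_h=float(phase[0]),
        extra={"n_shapes": n_shapes},
    )
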