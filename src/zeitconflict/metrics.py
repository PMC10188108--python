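"""Dark/light activity contrasts and group-level comparisons.

The dark-light contrast is the difference, in percentage points (or cm/h),
between mean activity during the dark and light phases of the cycle,
computed on un-normalized activity. Group comparisons of hourly activity
use a linear mixed model with a per-animal random intercept and AR(1)
residual correlation within animal, fitted by REML; rhythm-strength
distributions are compared with Kruskal-Wallis + Dunn post-hoc tests and
Levene's test (median-centered) for variance differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .tracks import ActivitySeries

__all__ = [
    "DarkLightContrast",
    "dark_light_contrast",
    "compare_contrast_groups",
    "compare_rhythm_strength",
    "dunn_posthoc",
]


@dataclass
class DarkLightContrast:
    animal_id: str
    pct_active_diff: float  # percentage points, dark mean - light mean
    distance_diff: float  # cm/h, dark mean - light mean


def dark_light_contrast(series: ActivitySeries, lights_on: int = 0,
                        lights_off: int = 12) -> DarkLightContrast:
    """Mean dark-phase minus mean light-phase activity for one animal.

    An hour bin belongs to the dark phase when its start hour mod 24 lies
    in [lights_off, 24), to the light phase in [lights_on, lights_off).
    """
    hmod = series.zt_hours % 24
    dark = (hmod >= lights_off)
    light = (hmod >= lights_on) & (hmod < lights_off)
    if not dark.any() or not light.any():
        raise ValueError("series must cover both light and dark phases")
    return DarkLightContrast(
        animal_id=series.animal_id,
        pct_active_diff=float(series.pct_active[dark].mean() - series.pct_active[light].mean()),
        distance_diff=float(series.distance_cm[dark].mean() - series.distance_cm[light].mean()),
    )


# ---------------------------------------------------------------------------
# mixed model: activity ~ phase * group, random intercept, AR(1) residuals
# ---------------------------------------------------------------------------

def _ar1_corr(T: int, rho: float) -> np.ndarray:
    idx = np.arange(T)
    return rho ** np.abs(idx[:, None] - idx[None, :])


class _RemlAr1:
    """REML fit of y = X beta + b_animal + e, e ~ AR(1) within animal."""

    def __init__(self, X, y, animal_idx):
        self.X = X
        self.y = y
        self.animal_idx = animal_idx
        self.animals = np.unique(animal_idx)

    def _neg_reml(self, theta):
        log_s2, log_s2b, z_rho = theta
        s2 = np.exp(log_s2)
        s2b = np.exp(log_s2b)
        rho = np.tanh(z_rho)
        XtVX = np.zeros((self.X.shape[1], self.X.shape[1]))
        XtVy = np.zeros(self.X.shape[1])
        ytVy = 0.0
        logdet = 0.0
        cache = {}
        for a in self.animals:
            m = self.animal_idx == a
            T = int(m.sum())
            if T not in cache:
                V = s2 * _ar1_corr(T, rho) + s2b * np.ones((T, T))
                sign, ld = np.linalg.slogdet(V)
                cache[T] = (np.linalg.inv(V), ld)
            Vi, ld = cache[T]
            Xa, ya = self.X[m], self.y[m]
            XtVX += Xa.T @ Vi @ Xa
            XtVy += Xa.T @ Vi @ ya
            ytVy += ya @ Vi @ ya
            logdet += ld
        sign, ld2 = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return 1e12
        beta = np.linalg.solve(XtVX, XtVy)
        quad = ytVy - beta @ XtVy
        return 0.5 * (logdet + ld2 + quad)

    def fit(self, tol: float = 1e-6):
        x0 = np.array([np.log(np.var(self.y) + 1e-8), np.log(np.var(self.y) / 4 + 1e-8), 0.0])
        res = optimize.minimize(self._neg_reml, x0, method="Nelder-Mead",
                                options={"xatol": tol, "fatol": tol, "maxiter": 2000})
        if not res.success:
            raise RuntimeError(f"REML optimization failed: {res.message}")
        log_s2, log_s2b, z_rho = res.x
        self.s2 = float(np.exp(log_s2))
        self.s2b = float(np.exp(log_s2b))
        self.rho = float(np.tanh(z_rho))
        XtVX = np.zeros((self.X.shape[1], self.X.shape[1]))
        XtVy = np.zeros(self.X.shape[1])
        cache = {}
        for a in self.animals:
            m = self.animal_idx == a
            T = int(m.sum())
            if T not in cache:
                V = self.s2 * _ar1_corr(T, self.rho) + self.s2b * np.ones((T, T))
                cache[T] = np.linalg.inv(V)
            Vi = cache[T]
            XtVX += self.X[m].T @ Vi @ self.X[m]
            XtVy += self.X[m].T @ Vi @ self.y[m]
        self.cov_beta = np.linalg.inv(XtVX)
        self.beta = self.cov_beta @ XtVy
        return self


def compare_contrast_groups(data: pd.DataFrame, value: str = "pct_active",
                            tol: float = 1e-6) -> dict:
    """Test whether the dark-light activity effect differs between groups.

    ``data`` is long-format with columns animal, group, hour (consecutive
    recording hour per animal), is_dark (bool), and the activity value.
    The model is value ~ is_dark * group with a random intercept per animal
    and AR(1) residual correlation within animal (hours ordered). The
    reported contrast per group pair is the difference in the dark-light
    effect; p-values are BH-adjusted. On a singular fit, falls back to
    Welch t-tests on per-animal contrasts with a warning.
    """
    need = {"animal", "group", "hour", "is_dark", value}
    if not need.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(need)}")
    groups = sorted(data["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if data.loc[data.group == g, "animal"].nunique() < 2:
            raise ValueError("each group needs at least 2 animals")
    df = data.sort_values(["animal", "hour"]).reset_index(drop=True)
    dark = df["is_dark"].to_numpy(float)
    gdum = pd.get_dummies(df["group"], drop_first=False)[groups].to_numpy(float)
    # columns: intercept, dark, group_2..k, dark:group_2..k
    X = np.column_stack(
        [np.ones(len(df)), dark]
        + [gdum[:, j] for j in range(1, len(groups))]
        + [dark * gdum[:, j] for j in range(1, len(groups))]
    )
    y = df[value].to_numpy(float)
    animal_idx = pd.factorize(df["animal"])[0]
    try:
        model = _RemlAr1(X, y, animal_idx).fit(tol=tol)
    except (RuntimeError, np.linalg.LinAlgError) as exc:
        warnings.warn(f"mixed model failed ({exc}); falling back to Welch "
                      "t-tests on per-animal contrasts")
        return _welch_fallback(df, value, groups)

    k = len(groups)
    # dark-light effect of group j: beta[1] (+ beta[1+(k-1)+j-1] for j>0)
    effects = {}
    eff_vectors = {}
    for j, g in enumerate(groups):
        v = np.zeros(X.shape[1])
        v[1] = 1.0
        if j > 0:
            v[1 + (k - 1) + j] = 1.0  # offset: interaction cols start at 1+(k-1)+1
        eff_vectors[g] = v
        effects[g] = float(v @ model.beta)
    pairs = [(groups[i], groups[j]) for i in range(k) for j in range(i + 1, k)]
    raw = []
    ests = []
    for g1, g2 in pairs:
        c = eff_vectors[g2] - eff_vectors[g1]
        est = float(c @ model.beta)
        se = float(np.sqrt(c @ model.cov_beta @ c))
        z = est / se if se > 0 else 0.0
        raw.append(2 * stats.norm.sf(abs(z)))
        ests.append(est)
    adj = multipletests(raw, method="fdr_bh")[1] if raw else []
    pairwise = pd.DataFrame(
        {"group1": [p[0] for p in pairs], "group2": [p[1] for p in pairs],
         "contrast": ests, "p_raw": raw, "p_adj": adj}
    )
    # omnibus interaction Wald test
    n_int = k - 1
    L = np.zeros((n_int, X.shape[1]))
    for j in range(n_int):
        L[j, 1 + (k - 1) + 1 + j] = 1.0
    est = L @ model.beta
    covL = L @ model.cov_beta @ L.T
    w = float(est @ np.linalg.solve(covL, est))
    p_int = float(stats.chi2.sf(w, n_int))
    return {
        "method": "reml_ar1",
        "p_interaction": p_int,
        "pairwise": pairwise,
        "effects": effects,
        "rho": model.rho,
        "sigma2": model.s2,
        "sigma2_animal": model.s2b,
    }


def _welch_fallback(df: pd.DataFrame, value: str, groups) -> dict:
    per_animal = (
        df.groupby(["group", "animal", "is_dark"])[value].mean().unstack("is_dark")
    )
    contrast = (per_animal[True] - per_animal[False]).rename("contrast").reset_index()
    pairs = [(groups[i], groups[j]) for i in range(len(groups))
             for j in range(i + 1, len(groups))]
    raw, ests = [], []
    for g1, g2 in pairs:
        a = contrast.loc[contrast.group == g1, "contrast"]
        b = contrast.loc[contrast.group == g2, "contrast"]
        res = stats.ttest_ind(b, a, equal_var=False)
        raw.append(float(res.pvalue))
        ests.append(float(b.mean() - a.mean()))
    adj = multipletests(raw, method="fdr_bh")[1] if raw else []
    pairwise = pd.DataFrame(
        {"group1": [p[0] for p in pairs], "group2": [p[1] for p in pairs],
         "contrast": ests, "p_raw": raw, "p_adj": adj}
    )
    return {"method": "welch_fallback", "p_interaction": float(min(raw)) if raw else 1.0,
            "pairwise": pairwise, "effects": {}, "rho": float("nan"),
            "sigma2": float("nan"), "sigma2_animal": float("nan")}


# ---------------------------------------------------------------------------
# rhythm-strength comparisons
# ---------------------------------------------------------------------------

def dunn_posthoc(groups: dict) -> pd.DataFrame:
    """Dunn's pairwise z-tests on ranks with tie correction, BH-adjusted."""
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    pooled = np.concatenate(values)
    N = len(pooled)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (N - 1))
    mean_ranks = {}
    pos = 0
    for g, v in zip(names, values):
        mean_ranks[g] = ranks[pos:pos + len(v)].mean()
        pos += len(v)
    pairs, raw, zs = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            g1, g2 = names[i], names[j]
            n1, n2 = len(groups[g1]), len(groups[g2])
            se = np.sqrt((N * (N + 1) / 12.0 - tie_term) * (1.0 / n1 + 1.0 / n2))
            z = (mean_ranks[g1] - mean_ranks[g2]) / se
            pairs.append((g1, g2))
            zs.append(z)
            raw.append(2 * stats.norm.sf(abs(z)))
    adj = multipletests(raw, method="fdr_bh")[1]
    return pd.DataFrame(
        {"group1": [p[0] for p in pairs], "group2": [p[1] for p in pairs],
         "z": zs, "p_raw": raw, "p_adj": adj}
    )


def compare_rhythm_strength(groups: dict) -> dict:
    """Kruskal-Wallis omnibus + Dunn pairwise + Levene variance test.

    ``groups`` maps group label -> array of per-animal rhythm strengths
    (e.g. peak Lomb-Scargle powers).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} needs at least 2 values")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    kw = stats.kruskal(*arrays)
    lev = stats.levene(*arrays, center="median")
    return {
        "p_omnibus": float(kw.pvalue),
        "statistic": float(kw.statistic),
        "pairwise": dunn_posthoc(groups),
        "p_levene": float(lev.pvalue),
    }
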