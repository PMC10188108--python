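"""Wavelet-based clustering of behavior profiles.

Smoothed mean activity profiles are decomposed with a continuous complex
Morlet transform (omega0 = 6) over a log-spaced period grid from 2 to 36 h;
pairwise dissimilarity between unit-power-normalized spectra (Frobenius
norm of the difference) feeds a PCA embedding; complete-linkage
hierarchical clustering of the embedding is scored with multiscale
bootstrap support: bootstrap proportions BP(r) at feature-resampling
scales r in {0.5, ..., 1.4} are fitted with the signed-root model
z(r) = v*sqrt(r) + c/sqrt(r) to yield approximately unbiased (AU)
p-values per internal node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from ._util import check_seed

__all__ = [
    "WaveletSpectrum",
    "ClusterResult",
    "wavelet_spectrum",
    "wavelet_distance_matrix",
    "pca_embed",
    "hcluster_au",
    "cluster_profiles",
    "linkage_to_newick",
]

_OMEGA0 = 6.0
_FC = _OMEGA0 / (2.0 * np.pi)  # Morlet center frequency in cycles per sample-period
_WAVELET = f"cmor2.0-{_FC:.12f}"


@dataclass
class WaveletSpectrum:
    label: str
    periods: np.ndarray  # hours
    times: np.ndarray  # hours
    power: np.ndarray  # period x time, non-negative, |W|^2
    coef: np.ndarray | None = None  # complex coefficients W (period x time)
    coi_flagged: bool = False  # series shorter than preferred for the largest period


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list
    node_leaves: list  # per internal node, frozenset of leaf indices
    bp: np.ndarray
    au: np.ndarray
    fit_v: np.ndarray
    fit_c: np.ndarray
    meta: dict = field(default_factory=dict)

    def cut(self, n_clusters: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")


def wavelet_spectrum(values, label: str = "series", dt_h: float = 1.0,
                     period_lo: float = 2.0, period_hi: float = 36.0,
                     n_periods: int = 48) -> WaveletSpectrum:
    """Continuous Morlet power spectrum of one series.

    Periods are log-spaced from ``period_lo`` to ``period_hi`` hours with
    at least 40 grid points; power is |W|^2. A constant series yields zero
    power everywhere (the transform has zero mean response).
    """
    y = np.asarray(values, dtype=float)
    if len(y) * dt_h < 2 * period_lo:
        raise ValueError("series too short for the smallest period")
    n_periods = max(40, n_periods)
    periods = np.geomspace(period_lo, period_hi, n_periods)
    coi_flagged = len(y) * dt_h < 2 * period_hi
    scales = _FC * periods / dt_h
    coef, freqs = pywt.cwt(y - y.mean(), scales, _WAVELET, sampling_period=dt_h)
    power = np.abs(coef) ** 2
    times = np.arange(len(y)) * dt_h
    return WaveletSpectrum(label=label, periods=periods, times=times,
                           power=power, coef=coef, coi_flagged=coi_flagged)


def wavelet_distance_matrix(spectra: list[WaveletSpectrum],
                            metric: str = "coefficient") -> np.ndarray:
    """Pairwise Frobenius dissimilarity between wavelet transforms.

    The default ``metric="coefficient"`` compares the complex coefficient
    matrices directly. It is sensitive to both spectral content and phase
    — wavelet *power* alone is blind to phase, so antiphase rhythms would
    be indistinguishable — and, because the input profiles are already on
    a common normalized activity scale, it deliberately skips per-spectrum
    rescaling: arrhythmic profiles have little coherent power and stay
    mutually close instead of being inflated to unit power.
    ``metric="coefficient_unit"`` rescales each coefficient matrix to unit
    total power; ``metric="power"`` compares unit-sum power matrices.
    """
    if not spectra:
        raise ValueError("no spectra")
    ref = spectra[0]
    mats = []
    for sp in spectra:
        if sp.power.shape != ref.power.shape or not np.allclose(sp.periods, ref.periods):
            raise ValueError("spectra are not on a common period/time grid")
        if metric in ("coefficient", "coefficient_unit"):
            m = sp.coef if sp.coef is not None else np.sqrt(sp.power)
            tot = (np.sqrt((np.abs(m) ** 2).sum())
                   if metric == "coefficient_unit" else 1.0)
        elif metric == "power":
            m = sp.power
            tot = m.sum()
        else:
            raise ValueError(f"unknown metric {metric!r}")
        mats.append(m / tot if tot > 0 else m)
    n = len(mats)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(mats[i] - mats[j]))
            D[i, j] = D[j, i] = d
    return D


def pca_embed(distance_matrix: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """PCA of the distance matrix, rows as feature vectors.

    Rows are centered (not scaled); all components with eigenvalue above
    ``tol`` are retained.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    if np.allclose(D, 0.0):
        return np.zeros((n, 1))
    pca = PCA(n_components=min(n - 1, n) or 1)
    coords = pca.fit_transform(D)
    keep = pca.explained_variance_ > tol
    if not keep.any():
        return np.zeros((n, 1))
    return coords[:, keep]


# ---------------------------------------------------------------------------
# complete-linkage + multiscale bootstrap AU
# ---------------------------------------------------------------------------

def _node_leaf_sets(Z: np.ndarray, n: int) -> list:
    sets = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, *_rest) in enumerate(Z):
        s = sets[int(a)] | sets[int(b)]
        sets[n + k] = s
        out.append(s)
    return out


def _cluster_leafsets(X: np.ndarray):
    Z = hierarchy.linkage(X, method="complete", metric="euclidean")
    return Z, _node_leaf_sets(Z, X.shape[0])


_SCALES = np.arange(0.5, 1.41, 0.1)


def hcluster_au(coords: np.ndarray, n_boot: int = 1000, seed: int = 0,
                labels: list | None = None) -> ClusterResult:
    """Complete-linkage clustering with multiscale-bootstrap AU support.

    Feature columns of ``coords`` are resampled with replacement at scales
    r in {0.5, 0.6, ..., 1.4} times the feature count, ``n_boot`` times
    each. Per internal node, the recovery proportion BP(r) is fitted with
    z(r) = v*sqrt(r) + c/sqrt(r) on the probit scale by weighted least
    squares, giving AU = 1 - Phi(v - c). Nodes recovered never/always at
    every scale get AU 0/1 without fitting; with a single feature column,
    AU is undefined and falls back to the plain BP.
    """
    X = np.asarray(coords, dtype=float)
    n, f = X.shape
    if n < 4:
        raise ValueError("need at least 4 observations")
    labels = labels if labels is not None else [str(i) for i in range(n)]
    Z, leafsets = _cluster_leafsets(X)
    rng = np.random.default_rng(check_seed(seed))

    counts = np.zeros((len(leafsets), len(_SCALES)))
    r_real = np.empty(len(_SCALES))
    for si, r in enumerate(_SCALES):
        fr = max(1, int(round(r * f)))
        r_real[si] = fr / f
        for _ in range(n_boot):
            cols = rng.integers(0, f, fr)
            _, ls = _cluster_leafsets(X[:, cols])
            found = set(ls)
            for ni, s in enumerate(leafsets):
                if s in found:
                    counts[ni, si] += 1
    bp_scales = counts / n_boot

    au = np.empty(len(leafsets))
    bp = bp_scales[:, np.argmin(np.abs(r_real - 1.0))]
    v_fit = np.full(len(leafsets), np.nan)
    c_fit = np.full(len(leafsets), np.nan)
    for ni in range(len(leafsets)):
        row = bp_scales[ni]
        if f < 2 or np.all(row >= 1.0):
            au[ni] = 1.0 if np.all(row >= 1.0) else bp[ni]
            continue
        if np.all(row <= 0.0):
            au[ni] = 0.0
            continue
        ok = (row > 0) & (row < 1)
        if ok.sum() < 2:
            au[ni] = bp[ni]
            continue
        r = r_real[ok]
        z = stats.norm.ppf(1.0 - row[ok])
        w = n_boot * stats.norm.pdf(z) ** 2 / (row[ok] * (1.0 - row[ok]))
        A = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        W = np.sqrt(w)
        sol, *_ = np.linalg.lstsq(A * W[:, None], z * W, rcond=None)
        v, c = sol
        v_fit[ni], c_fit[ni] = v, c
        au[ni] = float(1.0 - stats.norm.cdf(v - c))

    # root always recovers; pin its support
    au[-1] = 1.0
    bp[-1] = 1.0
    return ClusterResult(
        linkage=Z, labels=list(labels), node_leaves=leafsets,
        bp=bp, au=au, fit_v=v_fit, fit_c=c_fit,
        meta={"n_boot": n_boot, "scales": _SCALES.tolist(),
              "distance": "unit-power Frobenius (complex coefficients)", "linkage": "complete"},
    )


def cluster_profiles(profiles: dict, dt_h: float = 1.0, period_lo: float = 2.0,
                     period_hi: float = 36.0, n_boot: int = 1000, seed: int = 0,
                     metric: str = "coefficient"):
    """Full pipeline: spectra -> distances -> PCA -> clustering with AU.

    ``profiles`` maps label -> smoothed mean activity series on a common
    hourly grid. Returns (ClusterResult, distance matrix, coordinates).
    """
    labels = list(profiles)
    spectra = [
        wavelet_spectrum(profiles[k], label=k, dt_h=dt_h,
                         period_lo=period_lo, period_hi=period_hi)
        for k in labels
    ]
    D = wavelet_distance_matrix(spectra, metric=metric)
    coords = pca_embed(D)
    result = hcluster_au(coords, n_boot=n_boot, seed=seed, labels=labels)
    return result, D, coords


def linkage_to_newick(result: ClusterResult, support: str = "au") -> str:
    """Serialize the cluster tree as Newick with AU (or BP) node supports."""
    Z = result.linkage
    n = len(result.labels)
    sup = result.au if support == "au" else result.bp

    def _node(i: int) -> str:
        if i < n:
            return str(result.labels[i]).replace(" ", "_")
        k = i - n
        a, b, h, _ = Z[k]
        left = _node(int(a))
        right = _node(int(b))
        return f"({left},{right}){sup[k]:.3f}:{h:.6f}"

    root = 2 * n - 2
    return _node(root) + ";"
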