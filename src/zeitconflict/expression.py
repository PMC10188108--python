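"""Rhythmic-transcriptome pipeline.

Counts are TMM-normalized and expressed as log2 counts-per-million; each
condition's samples are screened for 24-h (possibly asymmetric) rhythms
with the umbrella test, folding the two sampled cycles mod 24; genes are
classified as shared / condition-specific / arrhythmic using a p<0.01
rhythmicity threshold with a marginal-significance exclusion band
(p<0.1 in the other condition disqualifies a gene from being
condition-specific); phase shifts between conditions are estimated by
cosinor comparison and attributed to the light vs the temperature cycle;
amplitudes and phase distributions are compared between conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import HOURS_PER_DAY, wrap_signed_hours
from .compare import (
    circular_homogeneity_test,
    cosinor_fit,
    cosinor_group_comparison,
    rayleigh_test,
)
from .rhythm import umbrella_screen_matrix

__all__ = [
    "ExpressionMatrix",
    "tmm_factors",
    "normalize_counts",
    "filter_low_counts",
    "screen_rhythmicity",
    "classify_genes",
    "phase_shift_analysis",
    "compare_amplitudes",
    "phase_distribution_tests",
]


@dataclass
class ExpressionMatrix:
    """Normalized log2-CPM values with the sampling design."""

    values: pd.DataFrame  # genes x samples
    design: pd.DataFrame  # sample_id, condition, zt_h, replicate
    norm_factors: pd.Series | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if list(self.values.columns) != list(self.design["sample_id"]):
            raise ValueError("design rows must match sample columns (same order)")

    def condition_slice(self, condition: str):
        m = self.design["condition"] == condition
        ids = self.design.loc[m, "sample_id"]
        return self.values[ids], self.design.loc[m]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair_factor(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
                     logratio_trim: float = 0.30, sum_trim: float = 0.05,
                     a_cutoff: float = -1e10) -> float:
    """Weighted trimmed mean of M-values of one library against the reference."""
    keep = (obs > 0) & (ref > 0)
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) + (lib_ref - ref[keep]) / (lib_ref * ref[keep])
    fin = np.isfinite(M) & np.isfinite(A) & (A > a_cutoff)
    M, A, w = M[fin], A[fin], w[fin]
    if len(M) == 0:
        return 1.0
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
    rank_m = stats.rankdata(M)
    rank_a = stats.rankdata(A)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(M[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, normalized to product 1.

    The reference library is the one whose 75th-percentile count fraction
    is closest to the mean of those fractions. Trims: 30% on M, 5% on A,
    with precision (inverse asymptotic variance) weights.
    """
    mat = counts.to_numpy(float)
    lib = mat.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("zero-count library")
    f75 = np.array([np.quantile(mat[:, j][mat[:, j] >= 0], 0.75) / lib[j]
                    for j in range(mat.shape[1])])
    ref_j = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array([
        _tmm_pair_factor(mat[:, j], mat[:, ref_j], lib[j], lib[ref_j])
        for j in range(mat.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def normalize_counts(counts: pd.DataFrame, design: pd.DataFrame,
                     prior_count: float = 0.5) -> ExpressionMatrix:
    """TMM-normalize raw counts and return log2(CPM + prior) values.

    CPM uses effective library sizes (raw library size times TMM factor),
    so with all factors equal to 1 each CPM column sums to exactly 1e6.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    factors = tmm_factors(counts)
    lib = counts.sum(axis=0)
    eff = lib * factors
    cpm = counts.div(eff, axis=1) * 1e6
    values = np.log2(cpm + prior_count)
    return ExpressionMatrix(values=values, design=design.reset_index(drop=True),
                            norm_factors=factors,
                            meta={"normalization": "TMM + log2(CPM+0.5)"})


def filter_low_counts(counts: pd.DataFrame, design: pd.DataFrame,
                      min_cpm: float = 1.0, min_samples: int = 3) -> pd.DataFrame:
    """Keep genes with CPM > min_cpm in >= min_samples samples of some condition."""
    lib = counts.sum(axis=0)
    cpm = counts.div(lib, axis=1) * 1e6
    keep = pd.Series(False, index=counts.index)
    for cond in design["condition"].unique():
        ids = design.loc[design.condition == cond, "sample_id"]
        keep |= (cpm[ids] > min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# rhythm screen and classification
# ---------------------------------------------------------------------------

def screen_rhythmicity(matrix: ExpressionMatrix, condition: str,
                       period: float = 24.0, asym_step_h: float = 4.0,
                       alpha: float = 0.01) -> pd.DataFrame:
    """Umbrella rhythm screen of every gene within one condition.

    The two sampled cycles are folded (times mod 24) so the second cycle
    acts as replication. Returns a per-gene frame with p_raw, p_adj
    (Bonferroni over waveform shapes), the umbrella z statistic, the best
    peak time, and the rhythmic flag at ``alpha`` on the adjusted p.
    """
    vals, des = matrix.condition_slice(condition)
    if vals.shape[1] < 12:
        raise ValueError("need at least 12 samples in the condition")
    if "zt_h" not in des.columns:
        raise ValueError("design lacks zt_h")
    tmod = np.round(des["zt_h"].to_numpy(float) % period, 9)
    uniq = np.unique(tmod)
    group_index = np.searchsorted(uniq, tmod)
    p_raw, p_adj, z, phase, n_shapes = umbrella_screen_matrix(
        vals.to_numpy(float), group_index, uniq, period, asym_step_h
    )
    return pd.DataFrame(
        {"p_raw": p_raw, "p_adj": p_adj, "statistic": z, "phase_h": phase,
         "rhythmic": p_adj < alpha},
        index=vals.index,
    )


def classify_genes(results_a: pd.DataFrame, results_b: pd.DataFrame,
                   p_rhythmic: float = 0.01, p_exclude: float = 0.1,
                   labels: tuple = ("shared", "a_specific", "b_specific"),
                   p_col: str = "p_adj") -> pd.Series:
    """Shared / condition-specific / arrhythmic classification.

    shared: p < p_rhythmic in both conditions; a_specific: p < p_rhythmic
    in A and p >= p_exclude in B (genes marginally significant in the
    other condition are excluded from the specific sets); b_specific
    symmetric; everything else arrhythmic/indeterminate. The result is a
    partition: every gene receives exactly one label.
    """
    if not results_a.index.equals(results_b.index):
        raise ValueError("result frames must share one gene universe")
    pa = results_a[p_col]
    pb = results_b[p_col]
    out = pd.Series("arrhythmic", index=results_a.index, name="class", dtype=object)
    out[(pa < p_rhythmic) & (pb < p_rhythmic)] = labels[0]
    out[(pa < p_rhythmic) & (pb >= p_exclude)] = labels[1]
    out[(pb < p_rhythmic) & (pa >= p_exclude)] = labels[2]
    indet = (((pa < p_rhythmic) & (pb >= p_rhythmic) & (pb < p_exclude))
             | ((pb < p_rhythmic) & (pa >= p_rhythmic) & (pa < p_exclude)))
    out[indet] = "indeterminate"
    return out


# ---------------------------------------------------------------------------
# phase shifts between conditions
# ---------------------------------------------------------------------------

def phase_shift_analysis(matrix: ExpressionMatrix, genes, condition_a: str,
                         condition_b: str, offset_h: float = 12.0,
                         period: float = 24.0, alpha: float = 0.01,
                         tracking_band: tuple = (10.0, 12.0)) -> pd.DataFrame:
    """Per-gene phase shift between conditions, on the light and temperature clocks.

    For every requested (shared rhythmic) gene a cosinor comparison between
    conditions estimates the signed shift ``d_phase_light`` on the lights-on
    clock; ``d_phase_temp`` = wrap(d_phase_light - offset) re-expresses it
    relative to the temperature cycle, which in the misaligned design lags
    the light cycle by ``offset_h``. A gene is flagged temperature-tracking
    when it shifted by 10-12 h on the light clock (p < alpha) but did not
    shift significantly relative to the temperature cycle.
    """
    va, da = matrix.condition_slice(condition_a)
    vb, db = matrix.condition_slice(condition_b)
    ta = da["zt_h"].to_numpy(float)
    tb = db["zt_h"].to_numpy(float)
    rows = []
    for gene in genes:
        cmpres = cosinor_group_comparison(ta, va.loc[gene].to_numpy(float),
                                          tb, vb.loc[gene].to_numpy(float), period)
        d_light = cmpres.d_phase_h
        d_temp = wrap_signed_hours(d_light - offset_h, period)
        se = cmpres.se_phase_h
        dof = max(1, len(ta) + len(tb) - 6)
        if np.isfinite(se) and se > 0:
            p_temp = 2.0 * stats.t.sf(abs(d_temp) / se, dof)
        else:
            p_temp = float("nan")
        lo, hi = tracking_band
        tracking = (
            lo <= abs(d_light) <= hi
            and cmpres.p_phase < alpha
            and not (np.isfinite(p_temp) and p_temp < alpha)
        )
        rows.append({
            "gene_id": gene,
            "d_phase_light": d_light,
            "d_phase_temp": d_temp,
            "p_phase_light": cmpres.p_phase,
            "p_phase_temp": p_temp,
            "se_phase_h": se,
            f"amplitude_{condition_a}": cmpres.fit1.amplitude,
            f"amplitude_{condition_b}": cmpres.fit2.amplitude,
            f"acrophase_{condition_a}": cmpres.fit1.acrophase_h,
            f"acrophase_{condition_b}": cmpres.fit2.acrophase_h,
            "temperature_tracking": tracking,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def compare_amplitudes(matrix: ExpressionMatrix, shared_genes,
                       condition_a: str, condition_b: str,
                       period: float = 24.0) -> dict:
    """Paired Wilcoxon on per-gene cosinor amplitudes of shared rhythmic genes.

    Amplitudes are on the log2-CPM scale. Reports the median percent
    change from condition A to B.
    """
    shared_genes = list(shared_genes)
    if len(shared_genes) < 2:
        raise ValueError("need at least 2 genes to compare amplitudes")
    va, da = matrix.condition_slice(condition_a)
    vb, db = matrix.condition_slice(condition_b)
    ta = da["zt_h"].to_numpy(float)
    tb = db["zt_h"].to_numpy(float)
    amp_a = np.array([cosinor_fit(ta, va.loc[g].to_numpy(float), period).amplitude
                      for g in shared_genes])
    amp_b = np.array([cosinor_fit(tb, vb.loc[g].to_numpy(float), period).amplitude
                      for g in shared_genes])
    diff = amp_b - amp_a
    if np.allclose(diff, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(amp_a, amp_b).pvalue)
    pct = 100.0 * (amp_b - amp_a) / np.where(amp_a > 0, amp_a, np.nan)
    return {
        "p": p,
        "median_pct_change": float(np.nanmedian(pct)),
        "amplitude_a": amp_a,
        "amplitude_b": amp_b,
    }


def mean_expression_test(matrix: ExpressionMatrix, genes_a, genes_b,
                         condition_a: str, condition_b: str) -> dict:
    """Unpaired Wilcoxon on mean expression of two condition-specific sets."""
    genes_a, genes_b = list(genes_a), list(genes_b)
    if len(genes_a) < 2 or len(genes_b) < 2:
        raise ValueError("need at least 2 genes per set")
    va, _ = matrix.condition_slice(condition_a)
    vb, _ = matrix.condition_slice(condition_b)
    ma = va.loc[genes_a].mean(axis=1).to_numpy()
    mb = vb.loc[genes_b].mean(axis=1).to_numpy()
    res = stats.mannwhitneyu(ma, mb, alternative="two-sided")
    return {"p": float(res.pvalue), "mean_a": float(ma.mean()), "mean_b": float(mb.mean())}


def phase_distribution_tests(phases_a, phases_b, n_mc: int = 10_000,
                             seed: int = 0) -> dict:
    """Uniformity (unimodal and axial/bimodal) and homogeneity of two phase sets.

    Rayleigh on the raw phases detects unimodal departures; Rayleigh on
    doubled phases (angles times 2) detects axial, i.e. bimodal-antipodal,
    structure. Homogeneity between conditions uses the Monte-Carlo
    label-permutation test on mean-vector dispersion.
    """
    a = np.asarray(phases_a, dtype=float)
    b = np.asarray(phases_b, dtype=float)
    if len(a) < 10 or len(b) < 10:
        raise ValueError("both samples need n >= 10")
    out = {}
    for name, ph in (("a", a), ("b", b)):
        out[f"p_rayleigh_{name}"] = rayleigh_test(ph)
        out[f"p_rayleigh_axial_{name}"] = rayleigh_test((2.0 * ph) % HOURS_PER_DAY)
    stat, p = circular_homogeneity_test(a, b, n_mc=n_mc, seed=seed)
    out["homogeneity_stat"] = stat
    out["p_homogeneity"] = p
    return out
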