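"""Sliding-window time-of-day enrichment of functional terms.

For every 4-h window of peak phase (24 hourly start times, windows taken
mod 24), genes peaking inside the window are compared against all other
genes per functional term with a one-sided Fisher exact test
(over-representation), BH-adjusted across terms within each window. The
hourly enrichment score of a term is the mean of -log10 adjusted p over
the three windows strictly containing that hour (starts t-3, t-2, t-1
mod 24: the score at ZT3 averages windows ZT0-4, ZT1-5 and ZT2-6), and an
hour counts as enriched when its score exceeds -log10(0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import HOURS_PER_DAY

__all__ = [
    "EnrichmentTrack",
    "window_term_test",
    "sliding_window_pvalues",
    "enrichment_score_track",
    "enrichment_peaks",
    "run_sliding_enrichment",
]

ALPHA_SCORE = -np.log10(0.05)


@dataclass
class EnrichmentTrack:
    term: str
    scores: np.ndarray  # 24 hourly values >= 0
    enriched: np.ndarray  # 24 booleans
    window_p_adj: dict = field(default_factory=dict)  # window start -> adjusted p


def _in_window(phases: np.ndarray, start: float, width: float) -> np.ndarray:
    """Half-open membership [start, start+width) on the 24-h circle."""
    rel = (phases - start) % HOURS_PER_DAY
    return rel < width


def window_term_test(gene_phases: pd.Series, membership: pd.DataFrame,
                     window_start: float, width_h: float = 4.0,
                     min_term_size: int = 5) -> pd.Series:
    """One-sided Fisher exact over-representation p per term for one window.

    ``gene_phases`` maps gene -> peak phase hour; ``membership`` has
    columns (gene, term). Terms with fewer than ``min_term_size`` member
    genes (within the phase universe) are dropped. An empty window yields
    p = 1 for every term.
    """
    genes = gene_phases.index
    phases = gene_phases.to_numpy(float)
    inw = _in_window(phases, window_start, width_h)
    M = len(genes)
    N = int(inw.sum())
    mem = membership[membership["gene"].isin(genes)]
    in_set = pd.Series(inw, index=genes)
    out = {}
    for term, sub in mem.groupby("term"):
        tg = sub["gene"].unique()
        n = len(tg)
        if n < min_term_size:
            continue
        if N == 0:
            out[term] = 1.0
            continue
        x = int(in_set[tg].sum())
        # over-representation: P(X >= x) under hypergeometric(M, n, N)
        out[term] = float(stats.hypergeom.sf(x - 1, M, n, N))
    return pd.Series(out, name=f"p_window_{window_start:g}").sort_index()


def sliding_window_pvalues(gene_phases: pd.Series, membership: pd.DataFrame,
                           width_h: float = 4.0, min_term_size: int = 5) -> pd.DataFrame:
    """Adjusted p-values for every term at each of the 24 window starts.

    BH adjustment runs across terms within each window (not across
    windows). Returns a term x 24 DataFrame of adjusted p.
    """
    cols = {}
    for start in range(int(HOURS_PER_DAY)):
        raw = window_term_test(gene_phases, membership, float(start), width_h,
                               min_term_size)
        if len(raw) == 0:
            raise ValueError("no terms pass the minimum size filter")
        adj = multipletests(raw.to_numpy(), method="fdr_bh")[1]
        cols[start] = pd.Series(adj, index=raw.index)
    return pd.DataFrame(cols)


def enrichment_score_track(window_p_adj: pd.Series | dict, term: str = "term",
                           alpha: float = 0.05) -> EnrichmentTrack:
    """Hourly enrichment score from 24 per-window adjusted p-values.

    score(t) = mean over window starts (t-3, t-2, t-1) mod 24 of
    -log10 p_adj; enriched(t) = score(t) > -log10(alpha).
    """
    p = pd.Series(window_p_adj)
    p.index = [int(i) % 24 for i in p.index]
    missing = set(range(24)) - set(p.index)
    if missing:
        raise ValueError(f"missing windows: {sorted(missing)}")
    neglog = -np.log10(p.sort_index().to_numpy(float))
    scores = np.empty(24)
    for t in range(24):
        contrib = [(t - 3) % 24, (t - 2) % 24, (t - 1) % 24]
        scores[t] = neglog[contrib].mean()
    thresh = -np.log10(alpha)
    return EnrichmentTrack(
        term=term, scores=scores, enriched=scores > thresh,
        window_p_adj={int(k): float(v) for k, v in p.sort_index().items()},
    )


def enrichment_peaks(track: EnrichmentTrack) -> list:
    """Peak hour and score of each contiguous enriched run (circular).

    Ties within a run resolve to the earliest hour of the run's circular
    traversal.
    """
    enr = track.enriched
    if not enr.any():
        return []
    if enr.all():
        runs = [list(range(24))]
    else:
        # start traversal just after a gap so circular runs stay contiguous
        start = int(np.flatnonzero(~enr)[0]) + 1
        runs = []
        cur = []
        for k in range(24):
            h = (start + k) % 24
            if enr[h]:
                cur.append(h)
            elif cur:
                runs.append(cur)
                cur = []
        if cur:
            runs.append(cur)
    out = []
    for run in runs:
        scores = track.scores[run]
        peak = run[int(np.argmax(scores))]
        out.append((track.term, peak, float(track.scores[peak])))
    return out


def run_sliding_enrichment(gene_phases: pd.Series, membership: pd.DataFrame,
                           width_h: float = 4.0, alpha: float = 0.05,
                           min_term_size: int = 5):
    """Score tracks and peaks for every term.

    Returns (score DataFrame term x 24, list of EnrichmentTrack, peaks list).
    """
    padj = sliding_window_pvalues(gene_phases, membership, width_h, min_term_size)
    tracks = []
    peaks = []
    for term, row in padj.iterrows():
        tr = enrichment_score_track(row, term=term, alpha=alpha)
        tracks.append(tr)
        peaks.extend(enrichment_peaks(tr))
    scores = pd.DataFrame(
        {tr.term: tr.scores for tr in tracks}
    ).T
    scores.columns = [f"ZT{h}" for h in range(24)]
    return scores, tracks, peaks
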