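"""Synthetic inputs with known ground truth.

Three generators emulate the two kinds of raw data the analysis consumes,
plus circular phase samples:

* bout-structured locomotor tracks — animals move in discrete bouts whose
  onset rate follows an inhomogeneous Poisson process
  lambda(t) = bout_rate_base * (1 + modulation_depth * cos(2*pi*(t - peak_phase_h)/24)),
  with tracking artifacts (low-likelihood dropouts, teleport glitches);
* negative-binomial count matrices over a 48-h, 4-h-resolution, replicated
  sampling design, with cosinor mean structure
  mu_g(t) = exp(m_g + a_g * cos(2*pi*(t - phi_g)/24)), condition-specific
  phase shifts, condition-specific rhythmic genes and arrhythmic genes;
* von Mises phase samples on the 24-h clock.

Every generator takes one seed and is fully deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import HOURS_PER_DAY, hours_to_radians, radians_to_hours, spawn_rngs
from .tracks import LocomotorTrack

__all__ = [
    "BehaviorSimConfig",
    "ExpressionSimConfig",
    "GroundTruth",
    "generate_tracks",
    "generate_expression",
    "generate_phase_sample",
]


@dataclass
class BehaviorSimConfig:
    """Parameters of the locomotor-track simulator.

    Defaults mirror the recording setup the pipeline targets: 2 frames/s
    over 72 h in a small arena, with nocturnal animals whose bout rate
    peaks at ZT18.
    """

    seed: int = 0
    n_animals: int = 18
    duration_h: float = 72.0
    fps: float = 2.0
    rhythmic_fraction: float = 1.0
    peak_phase_h: float = 18.0
    bout_rate_base: float = 2.0  # bouts per hour, time-averaged
    modulation_depth: float = 0.8
    bout_speed_cm_s: float = 0.06
    bout_mean_dur_s: float = 30.0
    dropout_prob: float = 0.01
    teleport_prob: float = 0.002
    arena_cm: float = 10.0
    zt_offset_h: float = 0.0

    def validate(self) -> None:
        if self.duration_h <= 0 or self.fps <= 0:
            raise ValueError("duration_h and fps must be positive")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        for name in ("rhythmic_fraction", "modulation_depth", "dropout_prob", "teleport_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.peak_phase_h < HOURS_PER_DAY:
            raise ValueError("peak_phase_h must lie in [0, 24)")
        if self.bout_rate_base < 0 or self.bout_speed_cm_s <= 0 or self.arena_cm <= 0:
            raise ValueError("rates, speeds and arena size must be positive")


@dataclass
class ExpressionSimConfig:
    """Parameters of the rhythmic count-matrix simulator.

    The default design is 13 time points every 4 h over 48 h with three
    replicates per time point in each of two conditions. Amplitudes a_g are
    on the natural-log scale of the cosinor mean; ``amplitude_range=(0.35,
    0.35)`` gives a 2-fold peak-to-trough ratio. ``phase_distribution`` maps
    each condition to a list of (mean_h, kappa, weight) von Mises mixture
    components for the rhythmic-gene acrophases.
    """

    seed: int = 0
    n_genes: int = 1000
    n_timepoints: int = 13
    timestep_h: float = 4.0
    n_replicates: int = 3
    conditions: tuple = ("Aligned", "SC")
    rhythmic_fraction: float = 0.3
    specific_fraction_a: float = 0.0  # rhythmic only in conditions[0]
    specific_fraction_b: float = 0.0  # rhythmic only in conditions[1]
    log_mean_range: tuple = (3.0, 8.0)  # natural log of baseline expression
    amplitude_range: tuple = (0.35, 0.35)
    dispersion: float = 0.1
    phase_distribution: dict = field(
        default_factory=lambda: {"Aligned": [(4.0, 3.0, 0.5), (14.0, 3.0, 0.5)]}
    )
    shift_fraction: float = 0.0  # rhythmic-in-both genes with +12 h phase in condition B
    shift_h: float = 12.0
    library_size_range: tuple = (0.8, 1.2)  # relative depth scalers

    def validate(self) -> None:
        if (self.n_timepoints - 1) * self.timestep_h < 48.0:
            raise ValueError("sampling design must cover at least 48 h")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        for name in ("rhythmic_fraction", "shift_fraction",
                     "specific_fraction_a", "specific_fraction_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.specific_fraction_a + self.specific_fraction_b > 1.0:
            raise ValueError("condition-specific fractions must sum to <= 1")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are supported")


@dataclass
class GroundTruth:
    """Planted truth for generated entities (one row per animal or gene)."""

    animals: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# locomotor tracks
# ---------------------------------------------------------------------------

def _bout_onsets(rng, cfg: BehaviorSimConfig, rhythmic: bool) -> np.ndarray:
    """Inhomogeneous-Poisson bout onset times (hours) by thinning."""
    depth = cfg.modulation_depth if rhythmic else 0.0
    lam_max = cfg.bout_rate_base * (1.0 + depth)
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * cfg.duration_h)
    cand = np.sort(rng.uniform(0.0, cfg.duration_h, n_cand))
    zt = (cfg.zt_offset_h + cand) % HOURS_PER_DAY
    lam = cfg.bout_rate_base * (
        1.0 + depth * np.cos(2.0 * np.pi * (zt - cfg.peak_phase_h) / HOURS_PER_DAY)
    )
    keep = rng.uniform(0.0, lam_max, n_cand) < lam
    return cand[keep]


def _simulate_animal(rng, cfg: BehaviorSimConfig, rhythmic: bool, animal_id: str) -> LocomotorTrack:
    n = int(round(cfg.duration_h * 3600.0 * cfg.fps))
    t = np.arange(n) / cfg.fps
    step = cfg.bout_speed_cm_s / cfg.fps  # cm per frame inside a bout

    onsets_h = _bout_onsets(rng, cfg, rhythmic)
    durations_s = rng.exponential(cfg.bout_mean_dur_s, len(onsets_h))

    moving = np.zeros(n, dtype=bool)
    for on_h, dur in zip(onsets_h, durations_s):
        i0 = int(on_h * 3600.0 * cfg.fps)
        i1 = min(n, i0 + max(1, int(round(dur * cfg.fps))))
        moving[i0:i1] = True

    # persistent-heading random walk inside bouts, stationary outside;
    # the unbounded path is folded into the arena by reflection, which is
    # 1-Lipschitz and so preserves the per-frame step bound
    heading = rng.uniform(0, 2 * np.pi) + np.cumsum(rng.normal(0.0, 0.3, n))
    dx = np.where(moving, step * np.cos(heading), 0.0)
    dy = np.where(moving, step * np.sin(heading), 0.0)
    dx[0] = dy[0] = 0.0
    a = cfg.arena_cm

    def _fold(p):
        return a - np.abs((p % (2 * a)) - a)

    x = _fold(a / 2.0 + np.cumsum(dx))
    y = _fold(a / 2.0 + np.cumsum(dy))

    likelihood = rng.uniform(0.95, 1.0, n)
    if cfg.dropout_prob > 0:
        drop = rng.random(n) < cfg.dropout_prob
        likelihood[drop] = rng.uniform(0.0, 0.90, int(drop.sum()))
    if cfg.teleport_prob > 0:
        tele = np.flatnonzero(rng.random(n) < cfg.teleport_prob)
        tele = tele[(tele > 0) & (tele < n - 1)]
        for i in tele:
            # single-frame excursion > 2 cm away, mimicking an identity glitch
            ang = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(2.5, 4.0)
            x[i] = np.clip(x[i] + r * np.cos(ang), -cfg.arena_cm, 2 * cfg.arena_cm)
            y[i] = np.clip(y[i] + r * np.sin(ang), -cfg.arena_cm, 2 * cfg.arena_cm)

    return LocomotorTrack(
        animal_id=animal_id, t=t, x=x, y=y,
        likelihood=likelihood, zt_offset_h=cfg.zt_offset_h,
    )


def generate_tracks(cfg: BehaviorSimConfig):
    """Simulate per-animal pose tracks.

    Returns (list of LocomotorTrack, GroundTruth) where the truth table has
    one row per animal with its rhythmicity flag and planted peak phase.
    """
    cfg.validate()
    rngs = spawn_rngs(cfg.seed, cfg.n_animals + 1)
    flag_rng, animal_rngs = rngs[0], rngs[1:]
    rhythmic = flag_rng.random(cfg.n_animals) < cfg.rhythmic_fraction
    tracks = []
    for i in range(cfg.n_animals):
        tracks.append(
            _simulate_animal(animal_rngs[i], cfg, bool(rhythmic[i]), f"animal{i:03d}")
        )
    truth = pd.DataFrame(
        {
            "animal_id": [tr.animal_id for tr in tracks],
            "is_rhythmic": rhythmic,
            "peak_phase_h": np.where(rhythmic, cfg.peak_phase_h, np.nan),
        }
    )
    return tracks, GroundTruth(animals=truth)


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def _draw_phases(rng, n: int, components) -> np.ndarray:
    """Sample n acrophases (hours) from a von Mises mixture on the 24-h clock."""
    comps = list(components)
    w = np.array([c[2] if len(c) > 2 else 1.0 for c in comps], dtype=float)
    w = w / w.sum()
    which = rng.choice(len(comps), size=n, p=w)
    out = np.empty(n)
    for k, (mu_h, kappa, *_rest) in enumerate(comps):
        m = which == k
        if kappa > 0:
            draws = rng.vonmises(hours_to_radians(mu_h), kappa, int(m.sum()))
        else:
            draws = rng.uniform(-np.pi, np.pi, int(m.sum()))
        out[m] = radians_to_hours(draws)
    return out


def generate_expression(cfg: ExpressionSimConfig):
    """Simulate a gene x sample count matrix with replicated circadian design.

    Returns (counts DataFrame, design DataFrame, GroundTruth). Counts are
    negative-binomial with mean mu_g(t) * library scaler and dispersion
    ``cfg.dispersion`` (variance mu + dispersion * mu^2). The design table
    has columns sample_id, condition, zt_h, replicate.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(int(cfg.seed)))
    cond_a, cond_b = cfg.conditions

    g = cfg.n_genes
    n_rhythmic = int(round(cfg.rhythmic_fraction * g))
    is_rhythmic = np.zeros(g, dtype=bool)
    is_rhythmic[:n_rhythmic] = True

    n_spec_a = int(round(cfg.specific_fraction_a * n_rhythmic))
    n_spec_b = int(round(cfg.specific_fraction_b * n_rhythmic))
    klass = np.array(["arrhythmic"] * g, dtype=object)
    klass[:n_spec_a] = "a_specific"
    klass[n_spec_a:n_spec_a + n_spec_b] = "b_specific"
    klass[n_spec_a + n_spec_b:n_rhythmic] = "shared"

    m_g = rng.uniform(*cfg.log_mean_range, g)
    a_g = np.where(is_rhythmic, rng.uniform(*cfg.amplitude_range, g), 0.0)

    comps = cfg.phase_distribution.get(cond_a) or next(iter(cfg.phase_distribution.values()))
    phase_a = np.where(is_rhythmic, _draw_phases(rng, g, comps), np.nan)
    phase_b = phase_a.copy()
    shared_idx = np.flatnonzero(klass == "shared")
    n_shift = int(round(cfg.shift_fraction * len(shared_idx)))
    shifted = np.zeros(g, dtype=bool)
    if n_shift:
        pick = shared_idx[:n_shift]
        phase_b[pick] = (phase_b[pick] + cfg.shift_h) % HOURS_PER_DAY
        shifted[pick] = True

    amp_a = np.where(klass == "b_specific", 0.0, a_g)
    amp_b = np.where(klass == "a_specific", 0.0, a_g)
    phase_a = np.where(amp_a > 0, phase_a, np.nan)
    phase_b = np.where(amp_b > 0, phase_b, np.nan)

    zts = np.arange(cfg.n_timepoints) * cfg.timestep_h
    rows = []
    for cond in cfg.conditions:
        for zt in zts:
            for rep in range(1, cfg.n_replicates + 1):
                rows.append((f"{cond}_ZT{int(zt):02d}_r{rep}", cond, float(zt), rep))
    design = pd.DataFrame(rows, columns=["sample_id", "condition", "zt_h", "replicate"])

    scalers = rng.uniform(*cfg.library_size_range, len(design))
    omega = 2.0 * np.pi / HOURS_PER_DAY
    counts = np.empty((g, len(design)), dtype=np.int64)
    nb_n = 1.0 / cfg.dispersion
    for j, (_, row) in enumerate(design.iterrows()):
        amp = amp_a if row.condition == cond_a else amp_b
        ph = phase_a if row.condition == cond_a else phase_b
        cosarg = np.where(np.isnan(ph), 0.0, np.cos(omega * (row.zt_h - np.nan_to_num(ph))))
        mu = np.exp(m_g + amp * cosarg) * scalers[j]
        p = nb_n / (nb_n + mu)
        counts[:, j] = rng.negative_binomial(nb_n, p)

    gene_ids = [f"gene{i:05d}" for i in range(g)]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=design["sample_id"])
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_rhythmic": is_rhythmic,
            "class": klass,
            "log_mean": m_g,
            "amplitude": a_g,
            f"phase_{cond_a}": phase_a,
            f"phase_{cond_b}": phase_b,
            "is_shifted": shifted,
        }
    ).set_index("gene_id")
    return counts_df, design, GroundTruth(genes=truth)


# ---------------------------------------------------------------------------
# phase samples
# ---------------------------------------------------------------------------

def generate_phase_sample(n: int, mu_h: float, kappa: float, seed: int) -> np.ndarray:
    """Draw n acrophases (hours in [0, 24)) from a von Mises distribution.

    ``kappa=0`` gives circular-uniform draws.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    if kappa == 0:
        return rng.uniform(0.0, HOURS_PER_DAY, n)
    return radians_to_hours(rng.vonmises(hours_to_radians(mu_h), kappa, n))
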