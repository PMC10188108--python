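import numpy as np
import pytest

from zeitconflict import synthetic, tracks


@pytest.fixture(scope="session")
def hourly_72():
    return np.arange(72.0)


@pytest.fixture(scope="session")
def small_tracks():
    """Three simulated animals at modest duration, with artifacts."""
    cfg = synthetic.BehaviorSimConfig(
        seed=11, n_animals=3, duration_h=48.0, dropout_prob=0.01,
        teleport_prob=0.001,
    )
    return synthetic.generate_tracks(cfg)


@pytest.fixture(scope="session")
def small_activity(small_tracks):
    trs, _ = small_tracks
    out = []
    for tr in trs:
        c = tracks.clean_track(tr)
        mask, _ = tracks.detect_movement(c)
        out.append(tracks.bin_hourly(c, mask))
    return out


def make_activity(animal_id, values, zt_hours=None):
    """ActivitySeries helper: norm_distance derived from values."""
    values = np.asarray(values, dtype=float)
    if zt_hours is None:
        zt_hours = np.arange(len(values))
    mx = values.max()
    return tracks.ActivitySeries(
        animal_id=animal_id,
        zt_hours=np.asarray(zt_hours, dtype=int),
        distance_cm=values,
        pct_active=100.0 * values / mx if mx > 0 else values,
        norm_distance=values / mx if mx > 0 else values,
        inactive=mx == 0,
    )
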