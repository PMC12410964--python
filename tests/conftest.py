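import numpy as np
import pytest

from flybeam import ChamberGeometry, FoodRegion, TrackingSeries
from flybeam.cleaning import CleanedSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def loco_geom():
    """23 x 15 mm locomotion chamber at 0.1 mm/px, long axis vertical."""
    return ChamberGeometry(x_min=0.0, y_min=0.0, x_max=150.0, y_max=230.0,
                           mm_per_px=0.1)


@pytest.fixture
def pref_geom():
    """50 x 10 mm two-food chamber, sugar at the low end, yeast at the high end."""
    return ChamberGeometry(
        x_min=0.0, y_min=0.0, x_max=100.0, y_max=500.0,
        food_regions=(FoodRegion("sugar", 0.0, 50.0), FoodRegion("yeast", 450.0, 500.0)),
        mm_per_px=0.1,
    )


def random_series(rng, n=200, geom=None, fps=5.0, oob_frac=0.0):
    """A random in-chamber trajectory with an optional fraction of far-out misdetections."""
    if geom is None:
        geom = ChamberGeometry(x_min=0.0, y_min=0.0, x_max=150.0, y_max=230.0)
    x = rng.uniform(geom.x_min, geom.x_max, n)
    y = rng.uniform(geom.y_min, geom.y_max, n)
    lik = rng.uniform(0.95, 1.0, n)
    if oob_frac > 0:
        bad = rng.random(n) < oob_frac
        x[bad] = geom.x_max + rng.uniform(1, 50, bad.sum())
        lik[bad] = rng.uniform(0, 0.5, bad.sum())
    return TrackingSeries(frames=np.arange(n), x=x, y=y, likelihood=lik, fps=fps)


def make_cleaned(frames, x, y, geom, fps=5.0, mask=None):
    """Construct a CleanedSeries directly (positions assumed in-chamber)."""
    frames = np.asarray(frames)
    n = len(frames)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    return CleanedSeries(
        frames=frames, x=np.asarray(x, float), y=np.asarray(y, float),
        likelihood=np.ones(n), interpolated_mask=mask, geometry=geom, fps=fps,
    )
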