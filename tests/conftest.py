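import numpy as np
import pytest

from sppa import ObservationWindow, BedSurfaceMap, SpecimenRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20190912)


@pytest.fixture
def unit_window():
    return ObservationWindow.rectangle(0.0, 0.0, 1.0, 1.0)


@pytest.fixture
def big_window():
    return ObservationWindow.rectangle(0.0, 0.0, 10.0, 10.0)


def make_map(points, taxa=None, window=None, name="test", **extra):
    """Build a BedSurfaceMap from an (n, 2) array quickly."""
    points = np.asarray(points, float)
    n = len(points)
    taxa = taxa if taxa is not None else ["Fractofusus_like"] * n
    if window is None:
        window = ObservationWindow.rectangle(
            points[:, 0].min() - 0.1, points[:, 1].min() - 0.1,
            points[:, 0].max() + 0.1, points[:, 1].max() + 0.1,
        )
    records = [
        SpecimenRecord(specimen_id=f"s{i}", taxon=t, x=float(p[0]), y=float(p[1]), **extra)
        for i, (p, t) in enumerate(zip(points, taxa))
    ]
    return BedSurfaceMap(name, records, window)


@pytest.fixture
def small_map(rng, big_window):
    pts = big_window.sample_uniform(40, rng)
    return make_map(pts, window=big_window)
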