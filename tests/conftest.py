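import numpy as np
import pytest

from cannuskill import CohortSpec, KinematicSeries, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Three participants x four trials; enough structure for pipeline tests."""
    spec = CohortSpec(n_participants=3, trials_per_participant=4)
    return simulate_cohort(spec, 11)


@pytest.fixture()
def entry_series():
    """Simple descending trajectory crossing skin_z=0 at a known sample."""
    n = 400
    t = np.arange(n) / 100.0
    z = np.linspace(5.0, -5.0, n)  # crosses 0 at sample 200
    return KinematicSeries(
        t=t, x=np.zeros(n), y=np.zeros(n), z=z, flash=np.zeros(n, dtype=int), fs=100.0
    )


def make_series(z, flash=None, fs=100.0, x=None, y=None):
    n = len(z)
    t = np.arange(n) / fs
    return KinematicSeries(
        t=t,
        x=np.zeros(n) if x is None else np.asarray(x, float),
        y=np.zeros(n) if y is None else np.asarray(y, float),
        z=np.asarray(z, float),
        flash=np.zeros(n, dtype=int) if flash is None else np.asarray(flash),
        fs=fs,
    )
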