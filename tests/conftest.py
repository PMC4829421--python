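import numpy as np
import pytest

from ranoise import flim_phasor as fp


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def decay_cube_from_hist(hist, rep_rate=80.0):
    """Wrap a 1-D histogram as a single-pixel DecayCube."""
    hist = np.asarray(hist)
    n_bins = hist.size
    return fp.DecayCube(
        counts=hist.reshape(n_bins, 1, 1).astype(np.int64),
        rep_rate=rep_rate,
        bin_width=1e3 / rep_rate / n_bins,
    )


def exponential_cube(tau, rep_rate=80.0, n_bins=256, total=10**7):
    """Noiseless sampled single-exponential decay as a DecayCube."""
    p = fp._wrapped_exponential(tau, rep_rate, n_bins)
    return decay_cube_from_hist(np.round(p * total).astype(np.int64), rep_rate)


@pytest.fixture
def two_refs():
    """RA (short lifetime) plus one background species at harmonic 1."""
    ra = fp.phasor_of_lifetime(0.35)
    bg = fp.phasor_of_lifetime(2.5)
    return fp.ReferenceSet(entries=(("RA", ra), ("background", bg)))
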