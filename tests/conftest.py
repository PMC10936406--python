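import numpy as np
import pytest

import semstack as ss


@pytest.fixture(scope="session")
def texture_512():
    """Default SEM-like texture used by the alignment tests."""
    return ss.make_textured_image((512, 512), seed=0)


@pytest.fixture(scope="session")
def texture_256():
    return ss.make_textured_image((256, 256), seed=1)


@pytest.fixture(scope="session")
def fig4_like():
    """One elongated dark charge center with asymmetric sigmoid tails.

    Emulates the lipid-droplet charging geometry: a flat background at 100
    intensity units, an elongated ellipse along the fast-scan axis, dark
    tails wider on one side than the other, and mild read noise.
    """
    img, mask, record = ss.make_charging_image(
        (256, 384), centers=((190, 128, 45, 12),),
        tail_params=[{"left": (-30.0, 6.0), "right": (-18.0, 12.0)}],
        noise_sigma=0.5, seed=0)
    return img, mask, record


@pytest.fixture(scope="session")
def bandlimited_half():
    """Noisy image pair sharing a ground truth cut hard at f = 0.5."""
    return ss.make_bandlimited_pair((512, 512), cutoff_norm=0.5, snr=10.0, seed=0)


def random_matchset(rng, n=40, lo=0.0, hi=500.0):
    src = rng.uniform(lo, hi, size=(n, 2))
    return src


def exact_matches(src, A, b):
    """MatchSet with destinations generated exactly by (A, b)."""
    src = np.asarray(src, dtype=np.float64)
    dst = src @ np.asarray(A, dtype=np.float64).T + np.asarray(b, dtype=np.float64)
    return ss.MatchSet(src, dst)
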