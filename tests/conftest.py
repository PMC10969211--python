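import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(20240311)


def brute_w2sq(xa, wa, xb, wb, n_grid=1_000_000):
    """Independent W2^2 oracle: midpoint-rule integration of the two step
    quantile functions on a dense grid of quantile levels."""
    xa, wa = np.asarray(xa, float), np.asarray(wa, float)
    xb, wb = np.asarray(xb, float), np.asarray(wb, float)
    oa, ob = np.argsort(xa, kind="stable"), np.argsort(xb, kind="stable")
    xa, ca = xa[oa], np.cumsum(wa[oa])
    xb, cb = xb[ob], np.cumsum(wb[ob])
    u = (np.arange(n_grid) + 0.5) / n_grid
    qa = xa[np.minimum(np.searchsorted(ca, u, side="left"), xa.size - 1)]
    qb = xb[np.minimum(np.searchsorted(cb, u, side="left"), xb.size - 1)]
    return float(np.mean((qa - qb) ** 2))


def simplex_grid_3(step=1e-3):
    """All weight vectors on the 2-simplex with the given step."""
    w1 = np.arange(0.0, 1.0 + step / 2, step)
    out = []
    for a in w1:
        b = np.arange(0.0, 1.0 - a + step / 2, step)
        w = np.column_stack([np.full(b.size, a), b, 1.0 - a - b])
        out.append(np.clip(w, 0.0, None))
    return np.vstack(out)
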