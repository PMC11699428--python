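"""Shared fixtures and the literal rule-transcription oracle."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("suite")


def literal_sweep(grid, delta, neighborhood="moore", right_to_left=True):
    """Unoptimized, literal transcription of the update rules.

    For the scanned element e0, S = sign(sum_q sign(e_q - e0)) over the
    neighbours that exist; then e0 <- e0 + S*delta clamped to [0, 255];
    agents are visited row by row from the top, right-to-left within each
    row (by default), and each update is immediately visible to later
    agents.  Kept deliberately naive and independent of the package's
    compiled implementation.
    """
    g = np.asarray(grid).astype(int).copy()
    m, n = g.shape
    if neighborhood == "moore":
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        offs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    cols = range(n - 1, -1, -1) if right_to_left else range(n)
    for i in range(m):
        for j in cols:
            total = 0
            for di, dj in offs:
                ni, nj = i + di, j + dj
                if 0 <= ni < m and 0 <= nj < n:
                    d = int(g[ni, nj]) - int(g[i, j])
                    total += int(d > 0) - int(d < 0)
            s = int(total > 0) - int(total < 0)
            g[i, j] = min(255, max(0, int(g[i, j]) + s * delta))
    return g.astype(np.uint8)


@pytest.fixture
def literal_sweep_oracle():
    return literal_sweep


def naive_objective(pixels, centroids, alpha_reg=0.6):
    """Per-pixel evaluation of the clustering objective (oracle).

    Every pixel is assigned to its nearest centroid (ties to the lowest
    centroid index) and contributes its squared distance; alpha_reg times
    the summed pairwise squared centroid separations is subtracted.
    """
    mu = list(map(float, centroids))
    intra = 0.0
    for x in np.asarray(pixels).ravel():
        d2 = [(float(x) - m) ** 2 for m in mu]
        intra += min(d2)
    sep = sum((mu[i] - mu[j]) ** 2
              for i in range(len(mu)) for j in range(i + 1, len(mu)))
    return intra - alpha_reg * sep


@pytest.fixture
def naive_objective_oracle():
    return naive_objective
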