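"""Independent oracles used by the tests.

These deliberately avoid the library's solve paths: 2x2 systems are solved
by Cramer's rule written out by hand, and the selection differential is
measured on raw truncated-normal draws.
"""

import numpy as np


def cramer2(A, y):
    """Solve a 2x2 linear system by Cramer's rule."""
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    return np.array([
        (y[0] * A[1, 1] - A[0, 1] * y[1]) / det,
        (A[0, 0] * y[1] - y[0] * A[1, 0]) / det,
    ])


def mc_upper_tail_mean(p, n_draws, seed):
    """Monte-Carlo mean of the upper-p tail of N(0,1), with its SE."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_draws)
    k = int(round(p * n_draws))
    top = np.partition(x, -k)[-k:]
    return top.mean(), top.std(ddof=1) / np.sqrt(k)


def random_psd_instance(rng, n=2, m=None):
    """A random well-conditioned (P, G, R, a, Q) instance.

    Built so that P = G + E with G and E both PSD, hence P - G is a valid
    environmental covariance and P dominates G (heritabilities below 1).
    """
    m = n if m is None else m
    A = rng.normal(size=(n, n))
    G_full = A @ A.T + 0.3 * np.eye(n)
    B = rng.normal(size=(n, n))
    E = B @ B.T + 0.3 * np.eye(n)
    P = G_full + E
    G = G_full[:, :m]
    R = np.eye(n)
    a = rng.uniform(0.2, 2.0, size=m)
    Q = rng.uniform(-1.0, 1.0, size=m)
    return P, G, R, a, Q
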