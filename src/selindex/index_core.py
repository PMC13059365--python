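"""Selection-index equations: weights, variance, gain, accuracy.

The aggregate genotype is H = a'g, the economically weighted sum of true
breeding values; an index I = b'X ranks candidates on phenotypic
measurements X.  Three weight constructions are provided:

* Smith-Hazel: b = P^-1 G a, the weights maximising corr(I, H);
* desired gains: b = (G'R)^-1 Q, forcing the q-generation response onto a
  breeder-chosen vector Q (square case, n = m);
* generalised desired gains: b = P^-1 R G [G' R P^-1 R G]^-1 Q, valid for
  n >= m and coinciding with the square solution when both exist.

Response to truncation selection follows the multi-trait breeder's
equation: per generation dG = (i/sigma_I) G'Rb with sigma_I = sqrt(b'Pb)
and i = phi(z_p)/p the standardised selection differential of the upper
fraction p of a normal distribution; over q generations with parameters
held constant the total change is q*dG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "SingularMatrixError",
    "IndexSolution",
    "SecondaryTraitSpec",
    "selection_intensity",
    "smith_hazel_weights",
    "desired_gains_weights",
    "generalized_desired_gains_weights",
    "index_sd",
    "expected_gain",
    "cumulative_gain",
    "correlated_response",
    "index_accuracy",
    "solve_index",
]

#: reciprocal-condition threshold below which a linear system is reported
#: as singular rather than solved
RCOND_SINGULAR = 1e-12

METHODS = ("smith_hazel", "desired_gains", "desired_gains_generalized")


class SingularMatrixError(np.linalg.LinAlgError):
    """A coefficient matrix is singular to working precision."""


def _solve(A: np.ndarray, rhs: np.ndarray, name: str) -> np.ndarray:
    """Solve A x = rhs with an explicit conditioning check."""
    A = np.asarray(A, dtype=float)
    rhs = np.asarray(rhs, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square, got shape {A.shape}")
    if A.shape[0] != rhs.shape[0]:
        raise ValueError(
            f"{name} shape {A.shape} does not conform with right-hand side "
            f"of length {rhs.shape[0]}"
        )
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or 1.0 / cond < RCOND_SINGULAR:
        raise SingularMatrixError(
            f"{name} is singular to working precision "
            f"(reciprocal condition {0.0 if not np.isfinite(cond) else 1.0 / cond:.3e})"
        )
    return np.linalg.solve(A, rhs)


def selection_intensity(p: float) -> float:
    """Standardised selection differential for selected proportion p.

    Mean of the upper-p tail of the standard normal, i = phi(z_p)/p with
    z_p the (1-p) quantile.  i(1) = 0 (no selection) and i is strictly
    decreasing in p.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"selection proportion must lie in (0, 1], got {p}")
    if p == 1.0:
        return 0.0
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def smith_hazel_weights(P: np.ndarray, G: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Smith-Hazel index weights b = P^-1 G a.

    Solves P b = G a; b is linear in the economic weights, so rescaling a
    by c > 0 rescales b by c without changing the ranking of candidates.
    """
    P = np.asarray(P, dtype=float)
    G = np.asarray(G, dtype=float)
    a = np.asarray(a, dtype=float)
    return _solve(P, G @ a, "phenotypic covariance matrix P")


def desired_gains_weights(G: np.ndarray, R: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Desired-gains weights b = (G'R)^-1 Q (square case, n = m).

    For a non-square G use :func:`generalized_desired_gains_weights`.
    """
    G = np.asarray(G, dtype=float)
    R = np.asarray(R, dtype=float)
    Q = np.asarray(Q, dtype=float)
    GtR = G.T @ R
    if GtR.shape[0] != GtR.shape[1]:
        raise ValueError(
            f"G'R has shape {GtR.shape}; the square-case solve needs n = m "
            "(use generalized_desired_gains_weights)"
        )
    return _solve(GtR, Q, "coefficient matrix G'R")


def generalized_desired_gains_weights(
    P: np.ndarray, R: np.ndarray, G: np.ndarray, Q: np.ndarray
) -> np.ndarray:
    """Generalised desired-gains weights b = P^-1 R G [G'R P^-1 R G]^-1 Q.

    The minimum-variance index achieving G'Rb = Q; reduces to the square
    solution when n = m and G'R is invertible.
    """
    P = np.asarray(P, dtype=float)
    R = np.asarray(R, dtype=float)
    G = np.asarray(G, dtype=float)
    Q = np.asarray(Q, dtype=float)
    RG = R @ G
    PinvRG = np.column_stack([
        _solve(P, RG[:, j], "phenotypic covariance matrix P")
        for j in range(RG.shape[1])
    ])
    inner = G.T @ R @ PinvRG
    y = _solve(inner, Q, "inner matrix G'R P^-1 R G")
    return PinvRG @ y


def index_sd(b: np.ndarray, P: np.ndarray) -> float:
    """Index standard deviation sigma_I = sqrt(b'Pb)."""
    b = np.asarray(b, dtype=float)
    P = np.asarray(P, dtype=float)
    quad = float(b @ P @ b)
    if quad < -1e-10 * max(1.0, float(np.abs(P).max())):
        raise ValueError(
            f"b'Pb = {quad:.6g} is negative: P is not positive semidefinite"
        )
    return float(np.sqrt(max(quad, 0.0)))


def expected_gain(
    b: np.ndarray, G: np.ndarray, R: np.ndarray, i_I: float, sigma_I: float
) -> np.ndarray:
    """Expected genetic gain per generation, dG = (i/sigma_I) G'Rb.

    Invariant under b -> c*b for c > 0 provided sigma_I is recomputed,
    since both G'Rb and sigma_I scale by c.
    """
    if sigma_I <= 0:
        raise ValueError(f"sigma_I must be > 0, got {sigma_I}")
    b = np.asarray(b, dtype=float)
    G = np.asarray(G, dtype=float)
    R = np.asarray(R, dtype=float)
    return (i_I / sigma_I) * (G.T @ (R @ b))


def cumulative_gain(dG, q: int):
    """Total change after q generations with constant parameters, q * dG."""
    if not (isinstance(q, (int, np.integer)) and q >= 0):
        raise ValueError(f"q must be a non-negative integer, got {q!r}")
    return q * np.asarray(dG, dtype=float)


@dataclass(frozen=True)
class SecondaryTraitSpec:
    """A trait outside the index whose correlated response is of interest.

    ``g_star`` holds the genetic covariances between each index measurement
    and the secondary trait.
    """

    name: str
    g_star: tuple

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "g_star", tuple(float(x) for x in self.g_star)
        )

    def as_array(self) -> np.ndarray:
        return np.asarray(self.g_star, dtype=float)


def correlated_response(
    b: np.ndarray,
    g_star: np.ndarray,
    R: np.ndarray,
    i_I: float,
    sigma_I: float,
    q: int = 4,
):
    """Response of a secondary trait to selection on the index.

    Per generation (i/sigma_I) g_star'Rb, and q times that in total.  When
    g_star is a column of G this reproduces the corresponding element of
    :func:`expected_gain`.  Returns ``(per_generation, total)``.
    """
    if sigma_I <= 0:
        raise ValueError(f"sigma_I must be > 0, got {sigma_I}")
    g_star = np.asarray(g_star, dtype=float)
    b = np.asarray(b, dtype=float)
    R = np.asarray(R, dtype=float)
    per_gen = float((i_I / sigma_I) * (g_star @ (R @ b)))
    return per_gen, float(q) * per_gen


def index_accuracy(
    b: np.ndarray,
    P: np.ndarray,
    a: np.ndarray,
    G: np.ndarray,
    mode: str = "ratio",
) -> float:
    """Accuracy of the index: its correlation with the aggregate genotype.

    ``mode="ratio"`` evaluates sqrt(b'Pb / a'Ga), which equals corr(I, H)
    when b is the Smith-Hazel solution (then b'Ga = b'Pb).  ``mode=
    "correlation"`` evaluates the general form b'Ga / sqrt(b'Pb * a'Ga),
    valid for arbitrary weights.
    """
    b = np.asarray(b, dtype=float)
    P = np.asarray(P, dtype=float)
    a = np.asarray(a, dtype=float)
    G = np.asarray(G, dtype=float)
    aGa = float(a @ G @ a)
    if aGa <= 0:
        raise ValueError(
            f"a'Ga = {aGa:.6g} must be > 0 (aggregate genotype has no "
            "genetic variance)"
        )
    bPb = float(b @ P @ b)
    if mode == "ratio":
        return float(np.sqrt(max(bPb, 0.0) / aGa))
    if mode == "correlation":
        if bPb <= 0:
            raise ValueError(f"b'Pb = {bPb:.6g} must be > 0 in mode 'correlation'")
        return float((b @ G @ a) / np.sqrt(bPb * aGa))
    raise ValueError(f"mode must be 'ratio' or 'correlation', got {mode!r}")


@dataclass(frozen=True)
class IndexSolution:
    """A solved index with its predicted response.

    ``dG`` is the per-generation gain vector, ``Q_total`` = q * dG the
    cumulative change, ``aggregate_per_gen`` the economically weighted gain
    a'dG (with the unweighted trait sum also kept), and
    ``desired_gains_factor`` the realised q * i / sigma_I for desired-gains
    solutions, whose normalisation nominally sets it to 1.
    """

    method: str
    b: np.ndarray
    sigma_I: float
    i_I: float
    p: float
    q: int
    dG: np.ndarray
    Q_total: np.ndarray
    rHI: Optional[float]
    a: Optional[np.ndarray] = None
    Q_target: Optional[np.ndarray] = None
    aggregate_per_gen: Optional[float] = None
    aggregate_total: Optional[float] = None
    sum_per_gen: float = 0.0
    sum_total: float = 0.0
    desired_gains_factor: Optional[float] = None

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "b": list(map(float, self.b)),
            "sigma_I": self.sigma_I,
            "i_I": self.i_I,
            "p": self.p,
            "q": self.q,
            "dG": list(map(float, self.dG)),
            "Q_total": list(map(float, self.Q_total)),
            "rHI": self.rHI,
            "sum_per_gen": self.sum_per_gen,
            "sum_total": self.sum_total,
        }
        if self.a is not None:
            out["a"] = list(map(float, self.a))
            out["aggregate_per_gen"] = self.aggregate_per_gen
            out["aggregate_total"] = self.aggregate_total
        if self.Q_target is not None:
            out["Q_target"] = list(map(float, self.Q_target))
            out["desired_gains_factor"] = self.desired_gains_factor
        return out


def solve_index(
    P: np.ndarray,
    G: np.ndarray,
    R: np.ndarray,
    p: float,
    q: int = 4,
    a: Optional[np.ndarray] = None,
    Q: Optional[np.ndarray] = None,
    method: str = "smith_hazel",
) -> IndexSolution:
    """Solve for index weights and the full predicted response.

    ``method`` selects the weight construction; Smith-Hazel requires
    economic weights ``a``, the desired-gains constructions require the
    target vector ``Q``.  Accuracy is reported whenever ``a`` is supplied
    (mode 'ratio' for Smith-Hazel weights, where it equals corr(I, H);
    mode 'correlation' otherwise).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    P = np.asarray(P, dtype=float)
    G = np.asarray(G, dtype=float)
    R = np.asarray(R, dtype=float)
    if method == "smith_hazel":
        if a is None:
            raise ValueError("smith_hazel requires economic weights a")
        b = smith_hazel_weights(P, G, a)
    elif method == "desired_gains":
        if Q is None:
            raise ValueError("desired_gains requires a target vector Q")
        b = desired_gains_weights(G, R, Q)
    else:
        if Q is None:
            raise ValueError("desired_gains_generalized requires a target vector Q")
        b = generalized_desired_gains_weights(P, R, G, Q)

    sigma_I = index_sd(b, P)
    i_I = selection_intensity(p)
    dG = expected_gain(b, G, R, i_I, sigma_I)
    Q_total = cumulative_gain(dG, q)

    rHI = None
    agg_pg = agg_tot = None
    a_arr = None
    if a is not None:
        a_arr = np.asarray(a, dtype=float)
        mode = "ratio" if method == "smith_hazel" else "correlation"
        rHI = index_accuracy(b, P, a_arr, G, mode=mode)
        agg_pg = float(a_arr @ dG)
        agg_tot = float(q) * agg_pg

    factor = None
    Q_arr = None
    if Q is not None:
        Q_arr = np.asarray(Q, dtype=float)
        factor = float(q) * i_I / sigma_I

    return IndexSolution(
        method=method, b=b, sigma_I=sigma_I, i_I=i_I, p=p, q=q,
        dG=dG, Q_total=Q_total, rHI=rHI, a=a_arr, Q_target=Q_arr,
        aggregate_per_gen=agg_pg, aggregate_total=agg_tot,
        sum_per_gen=float(dG.sum()), sum_total=float(Q_total.sum()),
        desired_gains_factor=factor,
    )
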