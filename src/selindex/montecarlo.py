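"""Stochastic validation of the deterministic index predictions.

Herds are simulated under the infinitesimal model that the index equations
assume: true breeding values g ~ N(0, G) and independent environmental
deviations e ~ N(0, P - G), phenotypes X = mu + g + e.  Truncation
selection on I = b'X then provides an empirical check of

* the predicted per-generation gain dG = (i/sigma_I) G'Rb, measured as the
  mean breeding value of the selected fraction minus the population mean
  (the change transmitted to the next generation when both sexes are
  selected identically);
* the index accuracy, measured as the sample correlation of I with the
  aggregate genotype H = a'g;
* the cumulative q-generation change q*dG under constant parameters,
  generations being discrete and non-overlapping with no Bulmer-effect
  variance reduction (deliberately, since the deterministic formulas ignore
  it too).

All randomness flows from one master seed through spawned child streams,
so every summary is reproducible bit-for-bit on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .index_core import expected_gain, index_sd, selection_intensity
from .parameters import ParameterSet, ScenarioSpec, apply_scenario

__all__ = [
    "SyntheticHerd",
    "SelectionRun",
    "MultiGenerationRun",
    "simulate_herd",
    "one_generation_response",
    "empirical_accuracy",
    "multi_generation_run",
]


def _mvn_factor(cov: np.ndarray, what: str) -> np.ndarray:
    """Square root of a (possibly singular) covariance matrix via eigh."""
    cov = np.asarray(cov, dtype=float)
    sym = (cov + cov.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    floor = -1e-8 * max(np.abs(vals).max(), 1.0)
    if vals.min() < floor:
        raise ValueError(
            f"{what} is not positive semidefinite "
            f"(smallest eigenvalue {vals.min():.6g})"
        )
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


@dataclass
class SyntheticHerd:
    """Individual-level herd: true breeding values and phenotypes.

    ``bv`` (n_individuals x m) are additive genetic values around zero,
    ``env`` the environmental deviations, ``phen = means + bv_offset + bv +
    env`` the phenotypes.  As n grows the sample covariance of ``bv``
    converges to G and that of ``phen`` to P.
    """

    trait_names: tuple
    bv: np.ndarray
    env: np.ndarray
    phen: np.ndarray
    generation: int = 0
    seed: Optional[object] = None

    @property
    def n(self) -> int:
        return self.bv.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"id": np.arange(self.n), "generation": self.generation}
        for k, name in enumerate(self.trait_names):
            cols[f"bv_{name}"] = self.bv[:, k]
            cols[f"phen_{name}"] = self.phen[:, k]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def simulate_herd(
    params: ParameterSet,
    n_individuals: int,
    seed: Union[int, np.random.Generator, None] = None,
    bv_offset: Optional[np.ndarray] = None,
) -> SyntheticHerd:
    """Draw a herd of ``n_individuals`` under the configured P and G.

    ``bv_offset`` shifts the breeding-value mean (used by the
    multi-generation runner to carry forward realised gains).
    """
    if n_individuals < 2:
        raise ValueError(f"need at least 2 individuals, got {n_individuals}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    G = params.G
    E = params.P - G
    Lg = _mvn_factor(G, "genetic covariance G")
    Le = _mvn_factor(E, "environmental covariance P - G")
    m = params.n_traits
    bv = rng.standard_normal((n_individuals, m)) @ Lg.T
    env = rng.standard_normal((n_individuals, m)) @ Le.T
    if bv_offset is not None:
        bv = bv + np.asarray(bv_offset, dtype=float)
    phen = params.means + bv + env
    return SyntheticHerd(trait_names=params.trait_names, bv=bv, env=env,
                         phen=phen, seed=seed)


@dataclass
class SelectionRun:
    """Replicated one-generation selection with prediction comparison.

    ``realized_se`` is the standard error across replicates; the z-scores
    locate the realised mean response relative to the deterministic
    prediction in SE units.
    """

    trait_names: tuple
    predicted_dG: np.ndarray
    realized_mean: np.ndarray
    realized_se: np.ndarray
    replicates: int
    n_individuals: int
    p: float
    per_replicate: Optional[np.ndarray] = None

    @property
    def z_scores(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return (self.realized_mean - self.predicted_dG) / self.realized_se

    def agrees(self, n_se: float = 3.0) -> bool:
        return bool(np.all(np.abs(self.z_scores) <= n_se))

    def to_dict(self) -> dict:
        return {
            "traits": list(self.trait_names),
            "predicted_dG": list(map(float, self.predicted_dG)),
            "realized_mean": list(map(float, self.realized_mean)),
            "realized_se": list(map(float, self.realized_se)),
            "z_scores": list(map(float, self.z_scores)),
            "replicates": self.replicates,
            "n_individuals": self.n_individuals,
            "p": self.p,
        }


def _select_top(I: np.ndarray, p: float) -> np.ndarray:
    n_sel = int(round(p * I.shape[0]))
    if n_sel < 1:
        raise ValueError(
            f"selected group is empty (p={p}, n={I.shape[0]})"
        )
    return np.argpartition(I, -n_sel)[-n_sel:]


def one_generation_response(
    params: ParameterSet,
    b: np.ndarray,
    p: float,
    n_individuals: int = 20_000,
    replicates: int = 100,
    seed: Union[int, np.random.SeedSequence, None] = None,
) -> SelectionRun:
    """Realised response of one round of truncation selection on I = b'X.

    Per replicate: simulate a herd, rank on the index, and record the mean
    breeding value of the top fraction ``p`` minus the population mean —
    the expected change in offspring mean under the infinitesimal model
    with both parents selected on the same index.
    """
    b = np.asarray(b, dtype=float)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    streams = [np.random.default_rng(s) for s in ss.spawn(replicates)]
    m = params.n_traits
    resp = np.empty((replicates, m))
    for r, rng in enumerate(streams):
        herd = simulate_herd(params, n_individuals, rng)
        I = herd.phen @ b
        sel = _select_top(I, p)
        resp[r] = herd.bv[sel].mean(axis=0) - herd.bv.mean(axis=0)
    sigma_I = index_sd(b, params.P)
    i_I = selection_intensity(p)
    predicted = expected_gain(b, params.G, params.R, i_I, sigma_I)
    se = (resp.std(axis=0, ddof=1) / np.sqrt(replicates)
          if replicates > 1 else np.full(m, np.nan))
    return SelectionRun(
        trait_names=params.trait_names, predicted_dG=predicted,
        realized_mean=resp.mean(axis=0), realized_se=se,
        replicates=replicates, n_individuals=n_individuals, p=p,
        per_replicate=resp,
    )


def empirical_accuracy(
    params: ParameterSet,
    b: np.ndarray,
    a: np.ndarray,
    n_individuals: int = 1_000_000,
    seed: Union[int, np.random.Generator, None] = None,
) -> float:
    """Sample correlation between the index I = b'X and H = a'g.

    For Smith-Hazel weights this converges to sqrt(b'Pb / a'Ga) as the
    herd grows.
    """
    herd = simulate_herd(params, n_individuals, seed)
    I = herd.phen @ np.asarray(b, dtype=float)
    H = herd.bv @ np.asarray(a, dtype=float)
    if I.std() == 0 or H.std() == 0:
        raise ValueError("index or aggregate genotype has zero variance")
    return float(np.corrcoef(I, H)[0, 1])


@dataclass
class MultiGenerationRun:
    """Realised cumulative gain over q discrete generations.

    ``cumulative_mean[g]`` is the mean realised cumulative change after
    generation g+1 across replicates; the prediction under constant
    parameters is (g+1) * predicted_dG.
    """

    trait_names: tuple
    predicted_dG: np.ndarray
    cumulative_mean: np.ndarray
    cumulative_se: np.ndarray
    q: int
    replicates: int
    n_per_generation: int

    @property
    def final_z_scores(self) -> np.ndarray:
        predicted_total = self.q * self.predicted_dG
        with np.errstate(divide="ignore", invalid="ignore"):
            return (self.cumulative_mean[-1] - predicted_total) / self.cumulative_se[-1]

    def agrees(self, n_se: float = 3.0) -> bool:
        return bool(np.all(np.abs(self.final_z_scores) <= n_se))


def multi_generation_run(
    params: ParameterSet,
    scenario: ScenarioSpec,
    q: int = 4,
    n_per_generation: int = 5_000,
    replicates: int = 50,
    seed: Union[int, np.random.SeedSequence, None] = None,
    method: str = "smith_hazel",
    Q: Optional[np.ndarray] = None,
) -> MultiGenerationRun:
    """Iterate truncation selection for q generations under a scenario.

    Each generation re-centres the breeding-value distribution by the
    realised change while holding G and P fixed (the constant-parameter
    premise of the q*dG prediction).  Weights are solved once from the
    scenario-adjusted parameters.
    """
    from .index_core import solve_index

    if q < 0:
        raise ValueError(f"q must be >= 0, got {q}")
    sp = apply_scenario(params, scenario)
    sol = solve_index(sp.P, sp.G, sp.R, p=scenario.p, q=max(q, 1),
                      a=scenario.a.as_array(), Q=Q, method=method)
    m = sp.n_traits
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    streams = [np.random.default_rng(s) for s in ss.spawn(max(replicates, 1))]
    cum = np.zeros((replicates, max(q, 1), m))
    for r, rng in enumerate(streams[:replicates]):
        offset = np.zeros(m)
        for g in range(q):
            herd = simulate_herd(sp, n_per_generation, rng, bv_offset=offset)
            I = herd.phen @ sol.b
            sel = _select_top(I, scenario.p)
            delta = herd.bv[sel].mean(axis=0) - herd.bv.mean(axis=0)
            offset = offset + delta
            cum[r, g] = offset
    if q == 0:
        cum = np.zeros((replicates, 0, m))
    mean = cum.mean(axis=0) if replicates else np.zeros((q, m))
    se = (cum.std(axis=0, ddof=1) / np.sqrt(replicates)
          if replicates > 1 else np.full((max(q, 0), m), np.nan))
    return MultiGenerationRun(
        trait_names=sp.trait_names, predicted_dG=sol.dG,
        cumulative_mean=mean, cumulative_se=se, q=q,
        replicates=replicates, n_per_generation=n_per_generation,
    )
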