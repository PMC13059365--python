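"""Genetic-parameter inputs and covariance-matrix assembly.

Everything downstream (index weights, gains, accuracies, simulation) consumes
two matrices built here from trait-level inputs:

``P``
    the n x n phenotypic covariance matrix between the index measurements X,
``G``
    the n x m genetic covariance matrix between the measurements and the
    breeding-goal traits (here the goal traits are the measured traits, so
    G is square and symmetric).

A diagonal relationship matrix ``R`` (Wright's coefficient of relationship
between the selection candidate and the relative supplying each record)
defaults to the identity: each candidate is scored on its own single record.

The module also ships the Huaxi cattle parameter fixture (12-month body
weight WEI-12 and daily milk yield DMY, estimated from 2,992 cows), a
consistency checker that surfaces internal conflicts in published parameter
tables without rejecting them, and the sensitivity-scenario machinery that
perturbs heritabilities and the genetic correlation.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import yaml

logger = logging.getLogger("selindex")

__all__ = [
    "TraitSpec",
    "TraitPairSpec",
    "EconomicWeights",
    "DesiredGains",
    "ScenarioSpec",
    "ParameterSet",
    "Config",
    "ConsistencyWarning",
    "ParameterError",
    "ConfigError",
    "build_matrices",
    "validate_consistency",
    "apply_scenario",
    "huaxi_parameters",
    "load_config",
    "save_config",
]


class ParameterError(ValueError):
    """Invalid genetic-parameter input (bound violation, bad dimension...)."""


class ConfigError(ParameterError):
    """Malformed or inconsistent configuration file."""


@dataclass(frozen=True)
class TraitSpec:
    """One trait: phenotypic moments, additive genetic variance, heritability.

    ``var_P`` is the phenotypic variance sigma^2_P, ``var_A`` the additive
    genetic variance V_A (both in squared trait units), ``h2`` the printed
    narrow-sense heritability.  ``h2`` and ``var_A / var_P`` need not agree:
    published tables are carried verbatim and conflicts are surfaced by
    :func:`validate_consistency`, not rejected.
    """

    name: str
    mean: float
    sd: float
    var_P: float
    var_A: float
    h2: float
    unit: str = "kg"
    n_records: Optional[int] = None
    h2_se: Optional[float] = None
    var_A_se: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.var_P > 0:
            raise ParameterError(
                f"trait {self.name!r}: var_P must be > 0, got {self.var_P}"
            )
        if self.var_A < 0:
            raise ParameterError(
                f"trait {self.name!r}: var_A must be >= 0, got {self.var_A}"
            )
        if not 0.0 <= self.h2 <= 1.0:
            raise ParameterError(
                f"trait {self.name!r}: h2 must lie in [0, 1], got {self.h2}"
            )
        if not self.sd > 0:
            raise ParameterError(
                f"trait {self.name!r}: sd must be > 0, got {self.sd}"
            )

    @property
    def h2_derived(self) -> float:
        """Heritability implied by the variance components, V_A / sigma^2_P."""
        return self.var_A / self.var_P


@dataclass(frozen=True)
class TraitPairSpec:
    """Genetic / environmental association between two traits.

    At least one of ``r_A`` (genetic correlation) or ``cov_G`` (genetic
    covariance) must be given; when both are, ``cov_G`` feeds matrix assembly
    directly and the pairing is cross-checked by :func:`validate_consistency`.
    ``cov_P`` may override the derived phenotypic covariance
    cov_G + r_E * sqrt(var_E_i * var_E_j).
    """

    trait_i: str
    trait_j: str
    r_A: Optional[float] = None
    cov_G: Optional[float] = None
    r_E: float = 0.0
    cov_P: Optional[float] = None

    def __post_init__(self) -> None:
        if self.r_A is None and self.cov_G is None:
            raise ParameterError(
                f"pair ({self.trait_i}, {self.trait_j}): "
                "one of r_A or cov_G is required"
            )
        if self.r_A is not None and not -1.0 <= self.r_A <= 1.0:
            raise ParameterError(
                f"pair ({self.trait_i}, {self.trait_j}): "
                f"r_A must lie in [-1, 1], got {self.r_A}"
            )
        if not -1.0 <= self.r_E <= 1.0:
            raise ParameterError(
                f"pair ({self.trait_i}, {self.trait_j}): "
                f"r_E must lie in [-1, 1], got {self.r_E}"
            )


@dataclass(frozen=True)
class EconomicWeights:
    """Relative economic weights a for the goal traits (dimensionless)."""

    a: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", tuple(float(x) for x in self.a))
        if not all(np.isfinite(self.a)):
            raise ParameterError(f"economic weights must be finite, got {self.a}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.a, dtype=float)

    def __len__(self) -> int:
        return len(self.a)


@dataclass(frozen=True)
class DesiredGains:
    """Breeder-specified total genetic changes Q over q generations."""

    Q: tuple
    q: int = 4

    def __post_init__(self) -> None:
        object.__setattr__(self, "Q", tuple(float(x) for x in self.Q))
        if not (isinstance(self.q, (int, np.integer)) and self.q >= 1):
            raise ParameterError(f"q must be an integer >= 1, got {self.q}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.Q, dtype=float)


@dataclass(frozen=True)
class ScenarioSpec:
    """One sensitivity condition: selection proportion, weights, perturbations.

    ``h2_modifier`` multiplies every trait's heritability (equivalently V_A,
    holding sigma^2_P fixed); a sequence gives per-trait multipliers.
    ``r_A_override`` replaces the genetic correlation of every pair.
    """

    id: str
    p: float
    a: EconomicWeights
    h2_modifier: Union[float, tuple] = 1.0
    r_A_override: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ParameterError(
                f"scenario {self.id!r}: selection proportion p must lie in "
                f"(0, 1), got {self.p}"
            )
        if not isinstance(self.a, EconomicWeights):
            object.__setattr__(self, "a", EconomicWeights(tuple(self.a)))
        if isinstance(self.h2_modifier, (list, tuple, np.ndarray)):
            object.__setattr__(
                self, "h2_modifier", tuple(float(m) for m in self.h2_modifier)
            )
        if self.r_A_override is not None and not -1.0 <= self.r_A_override <= 1.0:
            raise ParameterError(
                f"scenario {self.id!r}: r_A_override must lie in [-1, 1], "
                f"got {self.r_A_override}"
            )

    def modifiers(self, n_traits: int) -> np.ndarray:
        """Per-trait heritability multipliers as a length-n array."""
        if isinstance(self.h2_modifier, tuple):
            if len(self.h2_modifier) != n_traits:
                raise ParameterError(
                    f"scenario {self.id!r}: {len(self.h2_modifier)} h2 "
                    f"modifiers for {n_traits} traits"
                )
            return np.asarray(self.h2_modifier, dtype=float)
        return np.full(n_traits, float(self.h2_modifier))

    @property
    def is_identity(self) -> bool:
        mods = self.h2_modifier
        flat = mods if isinstance(mods, tuple) else (mods,)
        return self.r_A_override is None and all(m == 1.0 for m in flat)


@dataclass(frozen=True)
class ConsistencyWarning:
    """One internal-consistency finding; informational, never fatal."""

    code: str
    message: str
    severity: str = "warning"

    def to_dict(self) -> dict:
        return {"code": self.code, "severity": self.severity,
                "message": self.message}


def build_matrices(
    traits: Sequence[TraitSpec],
    pairs: Sequence[TraitPairSpec],
    r_override: Optional[float] = None,
):
    """Assemble the phenotypic (P) and genetic (G) covariance matrices.

    G[i, i] = V_A,i and G[i, j] = cov_G(i, j), taking the supplied covariance
    when present and r_A * sqrt(V_A,i * V_A,j) otherwise.  P[i, i] =
    sigma^2_P,i and P[i, j] = cov_G + r_E * sqrt(var_E_i * var_E_j) with
    var_E = sigma^2_P - V_A (unless the pair overrides cov_P).  When
    ``r_override`` is given it replaces every pair's genetic correlation and
    covariances are rebuilt from it.
    """
    names = [t.name for t in traits]
    if len(set(names)) != len(names):
        raise ParameterError(f"duplicate trait names: {names}")
    idx = {name: k for k, name in enumerate(names)}
    n = len(traits)
    P = np.zeros((n, n))
    G = np.zeros((n, n))
    for k, t in enumerate(traits):
        if t.var_A > t.var_P:
            raise ParameterError(
                f"trait {t.name!r}: environmental variance is negative "
                f"(var_A {t.var_A} > var_P {t.var_P})"
            )
        P[k, k] = t.var_P
        G[k, k] = t.var_A
    for pair in pairs:
        for name in (pair.trait_i, pair.trait_j):
            if name not in idx:
                raise ParameterError(f"pair references unknown trait {name!r}")
        i, j = idx[pair.trait_i], idx[pair.trait_j]
        ti, tj = traits[i], traits[j]
        scale_A = np.sqrt(ti.var_A * tj.var_A)
        if r_override is not None:
            cov_g = r_override * scale_A
        elif pair.cov_G is not None:
            cov_g = pair.cov_G
        else:
            cov_g = pair.r_A * scale_A
        var_E_i = ti.var_P - ti.var_A
        var_E_j = tj.var_P - tj.var_A
        if pair.cov_P is not None:
            cov_p = pair.cov_P
        else:
            cov_p = cov_g + pair.r_E * np.sqrt(var_E_i * var_E_j)
        G[i, j] = G[j, i] = cov_g
        P[i, j] = P[j, i] = cov_p
    return P, G


@dataclass(frozen=True)
class ParameterSet:
    """Validated trait parameters plus the derived P, G and R matrices.

    Trait order fixes the indexing of every matrix and vector downstream
    (weights b, economic weights a, desired gains Q, per-trait gains).
    ``h2_source`` selects which heritability value feeds computations that
    consume h2 itself: the ``printed`` column or the ``derived`` ratio
    V_A / sigma^2_P (matrices always use the variances directly).
    """

    traits: tuple
    pairs: tuple = ()
    relationship: Optional[np.ndarray] = None
    h2_source: str = "printed"
    r_override: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "traits", tuple(self.traits))
        object.__setattr__(self, "pairs", tuple(self.pairs))
        if self.h2_source not in ("printed", "derived"):
            raise ParameterError(
                f"h2_source must be 'printed' or 'derived', got {self.h2_source!r}"
            )
        P, G = build_matrices(self.traits, self.pairs, self.r_override)
        n = len(self.traits)
        if self.relationship is None:
            R = np.eye(n)
        else:
            R = np.asarray(self.relationship, dtype=float)
            if R.ndim == 1:
                R = np.diag(R)
            if R.shape != (n, n):
                raise ParameterError(
                    f"relationship matrix shape {R.shape} does not match "
                    f"{n} traits"
                )
            d = np.diag(R)
            if np.any(d <= 0) or np.any(d > 1):
                raise ParameterError(
                    "relationship matrix diagonal must lie in (0, 1], "
                    f"got {d}"
                )
        R.setflags(write=False)
        P.setflags(write=False)
        G.setflags(write=False)
        object.__setattr__(self, "relationship", R)
        object.__setattr__(self, "_P", P)
        object.__setattr__(self, "_G", G)

    # matrices -----------------------------------------------------------
    @property
    def P(self) -> np.ndarray:
        return self._P

    @property
    def G(self) -> np.ndarray:
        return self._G

    @property
    def R(self) -> np.ndarray:
        return self.relationship

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def trait_names(self) -> tuple:
        return tuple(t.name for t in self.traits)

    @property
    def means(self) -> np.ndarray:
        return np.array([t.mean for t in self.traits])

    def effective_h2(self) -> np.ndarray:
        """Heritabilities per ``h2_source`` (printed column or V_A ratio)."""
        if self.h2_source == "printed":
            return np.array([t.h2 for t in self.traits])
        return np.array([t.h2_derived for t in self.traits])

    def __eq__(self, other) -> bool:  # ndarray fields defeat dataclass eq
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return (
            self.traits == other.traits
            and self.pairs == other.pairs
            and self.h2_source == other.h2_source
            and self.r_override == other.r_override
            and np.array_equal(self.relationship, other.relationship)
        )


def validate_consistency(
    params: ParameterSet, tolerance: float = 0.01
) -> list:
    """Cross-check the parameter set and return a list of warnings.

    Checks, per trait, |h2 - V_A / sigma^2_P| <= tolerance; per pair,
    |cov_G - r_A * sqrt(V_A,i V_A,j)| <= tolerance * sqrt(V_A,i V_A,j); and
    positive semidefiniteness of the environmental covariance P - G.  Never
    raises: published tables are allowed to be internally inconsistent, and
    the caller decides what to do about it.  Warnings are also logged to
    standard error.
    """
    warnings: list = []
    for t in params.traits:
        ratio = t.h2_derived
        if abs(t.h2 - ratio) > tolerance:
            warnings.append(ConsistencyWarning(
                code="h2_mismatch",
                message=(
                    f"trait {t.name!r}: printed h2 {t.h2} differs from "
                    f"var_A/var_P = {ratio:.4f}"
                ),
            ))
    idx = {t.name: t for t in params.traits}
    for pair in params.pairs:
        if pair.r_A is None or pair.cov_G is None:
            continue
        scale = np.sqrt(idx[pair.trait_i].var_A * idx[pair.trait_j].var_A)
        implied = pair.r_A * scale
        if abs(pair.cov_G - implied) > tolerance * max(scale, 1e-300):
            warnings.append(ConsistencyWarning(
                code="cov_G_mismatch",
                message=(
                    f"pair ({pair.trait_i}, {pair.trait_j}): cov_G "
                    f"{pair.cov_G} differs from r_A*sqrt(V_A,i*V_A,j) = "
                    f"{implied:.4f}"
                ),
            ))
    E = params.P - params.G
    eigvals = np.linalg.eigvalsh((E + E.T) / 2.0)
    floor = -tolerance * max(np.abs(eigvals).max(), 1e-300)
    if eigvals.min() < floor:
        warnings.append(ConsistencyWarning(
            code="environment_not_psd",
            message=(
                "P - G (environmental covariance) is not positive "
                f"semidefinite; smallest eigenvalue {eigvals.min():.6g}"
            ),
        ))
    for w in warnings:
        logger.warning("%s: %s", w.code, w.message)
    return warnings


def warnings_to_json(warnings: Sequence[ConsistencyWarning]) -> str:
    """Machine-readable dump of a warning list."""
    return json.dumps([w.to_dict() for w in warnings], indent=2)


def apply_scenario(params: ParameterSet, scenario: ScenarioSpec) -> ParameterSet:
    """Return a new ParameterSet with the scenario's perturbations applied.

    Heritability modifiers rescale V_A holding sigma^2_P fixed (so h2 scales
    by the modifier).  An r_A override replaces the genetic correlation of
    every pair.  Under any perturbation, pair covariances are rebuilt from
    the governing correlation and the rescaled variances (the correlation is
    the structural parameter); an identity scenario returns parameters equal
    to the input, supplied covariances untouched.  The input is never
    modified.
    """
    if scenario.is_identity:
        return replace(params)
    mods = scenario.modifiers(params.n_traits)
    h2_eff = params.effective_h2()
    new_traits = []
    for t, m, h2 in zip(params.traits, mods, h2_eff):
        new_h2 = h2 * m
        if not 0.0 <= new_h2 <= 1.0:
            raise ParameterError(
                f"scenario {scenario.id!r}: modified h2 {new_h2:.4f} for "
                f"trait {t.name!r} lies outside [0, 1]"
            )
        printed_h2 = t.h2 * m
        new_traits.append(replace(
            t,
            var_A=t.var_A * m,
            h2=min(max(printed_h2, 0.0), 1.0),
        ))
    trait_by_name = {t.name: t for t in params.traits}
    new_pairs = []
    for pair in params.pairs:
        if scenario.r_A_override is not None:
            r_a = scenario.r_A_override
        elif pair.r_A is not None:
            r_a = pair.r_A
        else:
            ti, tj = trait_by_name[pair.trait_i], trait_by_name[pair.trait_j]
            r_a = pair.cov_G / np.sqrt(ti.var_A * tj.var_A)
        # covariances rebuilt from r_a and the rescaled variances
        new_pairs.append(replace(pair, r_A=float(r_a), cov_G=None,
                                 cov_P=None))
    return replace(params, traits=tuple(new_traits), pairs=tuple(new_pairs))


def huaxi_parameters(h2_source: str = "printed") -> ParameterSet:
    """Built-in genetic parameters for the Huaxi cattle study herd.

    Two goal traits estimated from 2,992 cows: 12-month body weight (WEI-12)
    and daily milk yield (DMY), with a genetic correlation of -0.15 and a
    genetic covariance of -0.75 between them.  Values are carried verbatim
    from the published table; the printed heritabilities (0.39 for both
    traits) disagree with the variance-component ratios, which
    :func:`validate_consistency` reports.  The relationship matrix is the
    identity (each candidate supplies its own single phenotypic record;
    Wright's r of an animal with itself is 1).
    """
    traits = (
        TraitSpec(name="WEI-12", unit="kg", n_records=2992, mean=357.15,
                  sd=28.1, var_P=789.61, var_A=11.21, h2=0.39),
        TraitSpec(name="DMY", unit="kg", n_records=2992, mean=28.50,
                  sd=5.9, var_P=34.81, var_A=2.25, h2=0.39),
    )
    pairs = (
        TraitPairSpec(trait_i="WEI-12", trait_j="DMY",
                      r_A=-0.15, cov_G=-0.75, r_E=0.0),
    )
    return ParameterSet(traits=traits, pairs=pairs, h2_source=h2_source)


# --------------------------------------------------------------------------
# configuration files
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Config:
    """A fully parsed analysis configuration."""

    parameters: ParameterSet
    scenarios: tuple = ()
    generations: int = 4
    desired_gains: Optional[DesiredGains] = None


_TRAIT_KEYS = {"name", "unit", "n_records", "mean", "sd", "var_P", "var_A",
               "h2", "h2_se", "var_A_se"}
_PAIR_KEYS = {"trait_i", "trait_j", "r_A", "cov_G", "r_E", "cov_P"}
_SCEN_KEYS = {"id", "p", "economic_weights", "h2_modifier", "r_A_override"}
_TOP_KEYS = {"traits", "pairs", "scenarios", "generations", "relationship",
             "h2_source", "desired_gains"}


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"{where}: unknown key(s) {sorted(unknown)}; "
            f"allowed keys are {sorted(allowed)}"
        )


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"{where}: missing required field {key!r}")
    return mapping[key]


def _number(value, key: str, where: str) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ConfigError(
            f"{where}: field {key!r} must be numeric, got {value!r}"
        ) from None
    if not np.isfinite(out):
        raise ConfigError(f"{where}: field {key!r} must be finite")
    return out


def load_config(path) -> Config:
    """Parse a YAML configuration into a :class:`Config`.

    Unknown keys are rejected with a message naming the key; missing or
    malformed fields raise :class:`ConfigError` naming the field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, str(path))

    traits = []
    for k, entry in enumerate(_require(raw, "traits", str(path))):
        where = f"traits[{k}]"
        _check_keys(entry, _TRAIT_KEYS, where)
        name = _require(entry, "name", where)
        kwargs = dict(
            name=str(name),
            mean=_number(_require(entry, "mean", where), "mean", where),
            sd=_number(_require(entry, "sd", where), "sd", where),
            var_P=_number(_require(entry, "var_P", where), "var_P", where),
            var_A=_number(_require(entry, "var_A", where), "var_A", where),
            h2=_number(_require(entry, "h2", where), "h2", where),
        )
        if "unit" in entry:
            kwargs["unit"] = str(entry["unit"])
        if entry.get("n_records") is not None:
            kwargs["n_records"] = int(entry["n_records"])
        for opt in ("h2_se", "var_A_se"):
            if entry.get(opt) is not None:
                kwargs[opt] = _number(entry[opt], opt, where)
        traits.append(TraitSpec(**kwargs))

    pairs = []
    for k, entry in enumerate(raw.get("pairs") or []):
        where = f"pairs[{k}]"
        _check_keys(entry, _PAIR_KEYS, where)
        kwargs = dict(
            trait_i=str(_require(entry, "trait_i", where)),
            trait_j=str(_require(entry, "trait_j", where)),
        )
        for opt in ("r_A", "cov_G", "r_E", "cov_P"):
            if entry.get(opt) is not None:
                kwargs[opt] = _number(entry[opt], opt, where)
        pairs.append(TraitPairSpec(**kwargs))

    relationship = None
    rel = raw.get("relationship", "identity")
    if rel not in (None, "identity"):
        relationship = np.asarray(rel, dtype=float)

    params = ParameterSet(
        traits=tuple(traits),
        pairs=tuple(pairs),
        relationship=relationship,
        h2_source=raw.get("h2_source", "printed"),
    )
    known = set(params.trait_names)
    for pair in pairs:
        for name in (pair.trait_i, pair.trait_j):
            if name not in known:
                raise ConfigError(
                    f"{path}: pair references unknown trait {name!r}"
                )

    scenarios = []
    for k, entry in enumerate(raw.get("scenarios") or []):
        where = f"scenarios[{k}]"
        _check_keys(entry, _SCEN_KEYS, where)
        weights = _require(entry, "economic_weights", where)
        if len(weights) != len(traits):
            raise ConfigError(
                f"{where}: {len(weights)} economic weights for "
                f"{len(traits)} traits"
            )
        kwargs = dict(
            id=str(_require(entry, "id", where)),
            p=_number(_require(entry, "p", where), "p", where),
            a=EconomicWeights(tuple(
                _number(w, "economic_weights", where) for w in weights
            )),
        )
        if entry.get("h2_modifier") is not None:
            mod = entry["h2_modifier"]
            if isinstance(mod, (list, tuple)):
                kwargs["h2_modifier"] = tuple(
                    _number(m, "h2_modifier", where) for m in mod
                )
            else:
                kwargs["h2_modifier"] = _number(mod, "h2_modifier", where)
        if entry.get("r_A_override") is not None:
            kwargs["r_A_override"] = _number(
                entry["r_A_override"], "r_A_override", where
            )
        scenarios.append(ScenarioSpec(**kwargs))

    generations = int(raw.get("generations", 4))
    if generations < 1:
        raise ConfigError(f"{path}: generations must be >= 1")

    desired = None
    if raw.get("desired_gains") is not None:
        desired = DesiredGains(
            Q=tuple(_number(x, "desired_gains", str(path))
                    for x in raw["desired_gains"]),
            q=generations,
        )
        if len(desired.Q) != len(traits):
            raise ConfigError(
                f"{path}: {len(desired.Q)} desired gains for "
                f"{len(traits)} traits"
            )

    return Config(parameters=params, scenarios=tuple(scenarios),
                  generations=generations, desired_gains=desired)


def save_config(config: Config, path) -> None:
    """Write a :class:`Config` back to YAML (round-trips with load_config)."""
    params = config.parameters
    doc: dict = {"traits": [], "pairs": [], "scenarios": []}
    for t in params.traits:
        entry = {"name": t.name, "unit": t.unit, "mean": t.mean, "sd": t.sd,
                 "var_P": t.var_P, "var_A": t.var_A, "h2": t.h2}
        if t.n_records is not None:
            entry["n_records"] = t.n_records
        if t.h2_se is not None:
            entry["h2_se"] = t.h2_se
        if t.var_A_se is not None:
            entry["var_A_se"] = t.var_A_se
        doc["traits"].append(entry)
    for pair in params.pairs:
        entry = {"trait_i": pair.trait_i, "trait_j": pair.trait_j}
        if pair.r_A is not None:
            entry["r_A"] = pair.r_A
        if pair.cov_G is not None:
            entry["cov_G"] = pair.cov_G
        if pair.r_E:
            entry["r_E"] = pair.r_E
        if pair.cov_P is not None:
            entry["cov_P"] = pair.cov_P
        doc["pairs"].append(entry)
    for s in config.scenarios:
        entry = {"id": s.id, "p": s.p, "economic_weights": list(s.a.a)}
        if not s.is_identity:
            if isinstance(s.h2_modifier, tuple):
                entry["h2_modifier"] = list(s.h2_modifier)
            elif s.h2_modifier != 1.0:
                entry["h2_modifier"] = s.h2_modifier
            if s.r_A_override is not None:
                entry["r_A_override"] = s.r_A_override
        doc["scenarios"].append(entry)
    doc["generations"] = config.generations
    doc["h2_source"] = params.h2_source
    if np.array_equal(params.relationship, np.eye(params.n_traits)):
        doc["relationship"] = "identity"
    else:
        doc["relationship"] = params.relationship.tolist()
    if config.desired_gains is not None:
        doc["desired_gains"] = list(config.desired_gains.Q)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
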