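"""Sensitivity scenarios and the scenario-by-trait gain report.

Nine built-in conditions (C1-C9) probe how the index responds to the
selected proportion, the economic weights, heritability (+/- 10%) and the
genetic correlation (overridden to -0.20).  ``run_scenarios`` evaluates any
scenario list against a parameter set and emits a tidy report with one row
per trait plus a "Cumulative" row per scenario; ``sensitivity_deltas``
differences the report against a baseline condition.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .index_core import SingularMatrixError, solve_index
from .parameters import (
    EconomicWeights,
    ParameterSet,
    ScenarioSpec,
    apply_scenario,
)

__all__ = [
    "GainReport",
    "builtin_scenarios",
    "run_scenarios",
    "sensitivity_deltas",
]

CUMULATIVE = "Cumulative"

REPORT_COLUMNS = [
    "scenario", "trait", "p", "economic_weight", "h2_modifier", "r_A",
    "b", "dG_per_gen", "dG_after_q", "rHI", "error",
]


def builtin_scenarios() -> list:
    """The nine built-in sensitivity conditions.

    C1/C2 vary the selected proportion (10% vs 20%) at weights (0.5, 1.0)
    for (WEI-12, DMY); C3/C4 swap the weights to (1, 0.5); C5/C6 weight both
    traits equally; C7/C8 scale heritability by +/-10% at the C1 setting;
    C9 overrides the genetic correlation to -0.20.
    """
    a_base = EconomicWeights((0.5, 1.0))
    a_swap = EconomicWeights((1.0, 0.5))
    a_even = EconomicWeights((1.0, 1.0))
    return [
        ScenarioSpec(id="C1", p=0.10, a=a_base),
        ScenarioSpec(id="C2", p=0.20, a=a_base),
        ScenarioSpec(id="C3", p=0.10, a=a_swap),
        ScenarioSpec(id="C4", p=0.20, a=a_swap),
        ScenarioSpec(id="C5", p=0.10, a=a_even),
        ScenarioSpec(id="C6", p=0.20, a=a_even),
        ScenarioSpec(id="C7", p=0.10, a=a_base, h2_modifier=1.10),
        ScenarioSpec(id="C8", p=0.10, a=a_base, h2_modifier=0.90),
        ScenarioSpec(id="C9", p=0.10, a=a_base, r_A_override=-0.20),
    ]


def _params_hash(params: ParameterSet) -> str:
    payload = repr((
        tuple((t.name, t.mean, t.sd, t.var_P, t.var_A, t.h2)
              for t in params.traits),
        tuple((p.trait_i, p.trait_j, p.r_A, p.cov_G, p.r_E, p.cov_P)
              for p in params.pairs),
        params.h2_source,
        params.relationship.tolist(),
    ))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class GainReport:
    """Scenario-by-trait report of index weights, gains and accuracy.

    ``table`` has one row per (scenario, trait) plus a Cumulative row whose
    per-generation and after-q entries are the economically weighted sums
    a'dG and q*a'dG; the plain trait sum is kept in ``sum_dG_per_gen`` /
    ``sum_dG_after_q`` on the same row.  Within every row
    ``dG_after_q = q * dG_per_gen``.
    """

    table: pd.DataFrame
    q: int
    method: str
    params_hash: str
    version: str

    def scenario_ids(self) -> list:
        return list(dict.fromkeys(self.table["scenario"]))

    def cumulative(self) -> pd.DataFrame:
        return self.table[self.table["trait"] == CUMULATIVE].set_index("scenario")

    # -- writers ---------------------------------------------------------
    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "q": self.q,
            "method": self.method,
            "params_hash": self.params_hash,
            "version": self.version,
            "rows": json.loads(self.table.to_json(orient="records")),
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
        return None

    def to_markdown(self, path=None, ndigits: int = 4):
        """Aligned markdown table; numbers displayed at report precision."""
        df = self.table.copy()
        num_cols = [c for c in df.columns
                    if c not in ("scenario", "trait", "error")]
        for col in num_cols:
            df[col] = df[col].map(
                lambda v: "" if pd.isna(v) else f"{v:.{ndigits}g}"
                if abs(v) < 1e-4 and v != 0 else
                "" if pd.isna(v) else f"{round(v, ndigits):g}"
            )
        df["error"] = df["error"].fillna("")
        cols = list(df.columns)
        rows = [[str(x) for x in rec] for rec in df.itertuples(index=False)]
        widths = [max(len(c), *(len(r[k]) for r in rows)) if rows else len(c)
                  for k, c in enumerate(cols)]
        def fmt(cells):
            return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
        lines = [fmt(cols), fmt(["-" * w for w in widths])]
        lines += [fmt(r) for r in rows]
        text = "\n".join(lines) + "\n"
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None


def run_scenarios(
    params: ParameterSet,
    scenarios: Optional[Sequence[ScenarioSpec]] = None,
    q: int = 4,
    method: str = "smith_hazel",
    Q: Optional[np.ndarray] = None,
) -> GainReport:
    """Evaluate every scenario against ``params`` and build a GainReport.

    Deterministic given its inputs.  Desired-gains methods need the target
    vector ``Q``.  A singular system in one scenario is recorded in that
    scenario's ``error`` column without aborting the rest of the run.
    """
    from . import __version__

    if scenarios is None:
        scenarios = builtin_scenarios()
    rows = []
    names = params.trait_names
    for scen in scenarios:
        mods = scen.modifiers(params.n_traits)
        try:
            sp = apply_scenario(params, scen)
            r_a_used = (scen.r_A_override if scen.r_A_override is not None
                        else (sp.pairs[0].r_A if sp.pairs else np.nan))
            sol = solve_index(
                sp.P, sp.G, sp.R, p=scen.p, q=q,
                a=scen.a.as_array(), Q=Q, method=method,
            )
        except (SingularMatrixError, ValueError) as exc:
            for trait in (*names, CUMULATIVE):
                rows.append(dict.fromkeys(REPORT_COLUMNS, np.nan)
                            | {"scenario": scen.id, "trait": trait,
                               "p": scen.p, "error": str(exc)})
            continue
        for k, trait in enumerate(names):
            rows.append({
                "scenario": scen.id, "trait": trait, "p": scen.p,
                "economic_weight": scen.a.a[k], "h2_modifier": mods[k],
                "r_A": r_a_used, "b": sol.b[k],
                "dG_per_gen": sol.dG[k], "dG_after_q": sol.Q_total[k],
                "rHI": sol.rHI, "error": None,
                "sum_dG_per_gen": np.nan, "sum_dG_after_q": np.nan,
            })
        rows.append({
            "scenario": scen.id, "trait": CUMULATIVE, "p": scen.p,
            "economic_weight": np.nan, "h2_modifier": np.nan,
            "r_A": r_a_used, "b": np.nan,
            "dG_per_gen": sol.aggregate_per_gen,
            "dG_after_q": sol.aggregate_total,
            "rHI": sol.rHI, "error": None,
            "sum_dG_per_gen": sol.sum_per_gen,
            "sum_dG_after_q": sol.sum_total,
        })
    table = pd.DataFrame(rows)
    ids = [s.id for s in scenarios]
    if len(set(ids)) != len(ids):
        raise ValueError(f"scenario ids must be unique, got {ids}")
    return GainReport(table=table, q=q, method=method,
                      params_hash=_params_hash(params), version=__version__)


def sensitivity_deltas(report: GainReport, baseline_id: str = "C1") -> pd.DataFrame:
    """Absolute and relative change of aggregate gain and accuracy vs baseline."""
    cum = report.cumulative()
    if baseline_id not in cum.index:
        raise KeyError(
            f"baseline scenario {baseline_id!r} not in report "
            f"(have {list(cum.index)})"
        )
    base = cum.loc[baseline_id]
    out = []
    for scen, row in cum.iterrows():
        d_gain = row["dG_per_gen"] - base["dG_per_gen"]
        d_rhi = row["rHI"] - base["rHI"]
        out.append({
            "scenario": scen,
            "d_aggregate_abs": d_gain,
            "d_aggregate_rel": d_gain / base["dG_per_gen"],
            "d_rHI_abs": d_rhi,
            "d_rHI_rel": d_rhi / base["rHI"],
        })
    return pd.DataFrame(out)
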