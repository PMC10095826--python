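"""Error and ranking metrics for binding-affinity tables.

Sign conventions, fixed by validation against the packaged reference table:

* MSE = mean(experimental - calculated): a negative MSE means the
  calculations overbind on average.
* Kendall tau is the plain pairwise statistic (concordant - discordant over
  all pairs; ties contribute zero).
* The predictive index weights each pair by the absolute *calculated*
  affinity difference; this is the only weighting that reproduces the
  reference PI row, so it is the default (``weight_by="calc"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AffinityTable",
    "ErrorMetrics",
    "apply_protonation_average",
    "error_metrics",
    "kendall_tau",
    "pearlman_pi",
    "metric_block",
    "round_half_away",
]


@dataclass
class AffinityTable:
    """Per-guest experimental and computed binding free energies (kcal/mol).

    ``frame`` columns: ``guest``, ``dg_exp``, then one ``dg_<model>`` (and
    optionally ``sd_<model>``) per parameter set.  Protonation variants of a
    guest appear as "<guest> <variant>" rows sharing one experimental value.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        for col in ("guest", "dg_exp"):
            if col not in self.frame.columns:
                raise ValueError(f"affinity table missing column {col!r}")
        if self.frame["dg_exp"].isna().any():
            raise ValueError("every guest needs an experimental value")

    @property
    def models(self) -> list:
        return [c[3:] for c in self.frame.columns
                if c.startswith("dg_") and c != "dg_exp"]

    def column(self, model: str) -> np.ndarray:
        return self.frame[f"dg_{model}"].to_numpy(dtype=float)

    @property
    def exp(self) -> np.ndarray:
        return self.frame["dg_exp"].to_numpy(dtype=float)


def apply_protonation_average(table: AffinityTable, guest: str,
                              variants=("prot", "deprot")) -> AffinityTable:
    """Collapse the protonation variants of one guest into a single row whose
    computed values are the arithmetic means of the variant rows."""
    df = table.frame
    names = [f"{guest} {v}" for v in variants]
    rows = df[df["guest"].isin(names)]
    if len(rows) != len(variants):
        missing = set(names) - set(rows["guest"])
        raise ValueError(f"missing protonation variants: {sorted(missing)}")
    exp_vals = rows["dg_exp"].unique()
    if len(exp_vals) != 1:
        raise ValueError("protonation variants must share one experimental value")
    merged = {"guest": guest, "dg_exp": float(exp_vals[0])}
    for col in df.columns:
        if col.startswith(("dg_", "sd_")) and col != "dg_exp":
            merged[col] = float(rows[col].mean())
    first = df.index[df["guest"] == names[0]][0]
    out = df[~df["guest"].isin(names)].copy()
    upper = out.loc[out.index < first]
    lower = out.loc[out.index >= first]
    out = pd.concat([upper, pd.DataFrame([merged]), lower], ignore_index=True)
    return AffinityTable(out)


@dataclass
class ErrorMetrics:
    mse: float
    mae: float
    rmse: float


def _paired(exp, calc):
    exp = np.asarray(exp, dtype=float)
    calc = np.asarray(calc, dtype=float)
    if exp.shape != calc.shape or exp.ndim != 1:
        raise ValueError("exp and calc must be 1-D arrays of equal length")
    return exp, calc


def error_metrics(exp, calc) -> ErrorMetrics:
    exp, calc = _paired(exp, calc)
    if exp.size < 1:
        raise ValueError("need at least one pair")
    d = exp - calc
    return ErrorMetrics(mse=float(d.mean()), mae=float(np.abs(d).mean()),
                        rmse=float(np.sqrt((d**2).mean())))


def kendall_tau(exp, calc) -> float:
    """(concordant - discordant) / total pairs; a tied pair contributes 0."""
    exp, calc = _paired(exp, calc)
    n = exp.size
    if n < 2:
        raise ValueError("need at least two values")
    if np.all(exp == exp[0]) or np.all(calc == calc[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    s = 0.0
    for i in range(n):
        s += np.sum(np.sign(exp[i + 1:] - exp[i]) * np.sign(calc[i + 1:] - calc[i]))
    return float(s / (n * (n - 1) / 2))


def pearlman_pi(exp, calc, weight_by: str = "calc") -> float:
    """Predictive index: pairwise order agreement weighted by affinity gaps.

    ``weight_by`` selects whether the pair weight |dG_j - dG_i| is taken from
    the calculated (default, matches the reference table) or the experimental
    values.  Pairs tied in ``calc`` contribute 0 to the numerator.
    """
    exp, calc = _paired(exp, calc)
    n = exp.size
    if n < 2:
        raise ValueError("need at least two values")
    src = {"calc": calc, "exp": exp}[weight_by]
    if np.all(src == src[0]):
        raise ValueError("predictive index undefined: all weights are zero")
    num = den = 0.0
    for i in range(n):
        de = exp[i + 1:] - exp[i]
        dc = calc[i + 1:] - calc[i]
        w = np.abs((src[i + 1:] - src[i]))
        num += np.sum(w * np.sign(de) * np.sign(dc))
        den += np.sum(w)
    return float(num / den)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (table precision convention)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def metric_block(table: AffinityTable, models=None,
                 average_guest: str = "G5") -> pd.DataFrame:
    """All five quality metrics for every model column of an affinity table.

    Protonation variants of ``average_guest`` (if present) are averaged
    first, so each model is scored on one row per guest.
    """
    if average_guest is not None and any(
            g.startswith(average_guest + " ") for g in table.frame["guest"]):
        table = apply_protonation_average(table, average_guest)
    models = models or table.models
    exp = table.exp
    out = {}
    for m in models:
        calc = table.column(m)
        em = error_metrics(exp, calc)
        out[m] = {
            "MSE": em.mse,
            "MAE": em.mae,
            "RMSE": em.rmse,
            "tau": kendall_tau(exp, calc),
            "PI": pearlman_pi(exp, calc),
        }
    return pd.DataFrame(out)
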