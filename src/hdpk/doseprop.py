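"""Dose-linearity assessment: dose-normalized comparisons and the power model.

The escalation gate works in two parts.  A Kruskal-Wallis test compares
dose-normalized Cmax and AUC_last across dose groups, and a power model
regresses ln(parameter) on ln(dose); exposure is declared dose-proportional
for a parameter when the 95% confidence interval of the log-log slope beta
contains 1.0.  The study proceeds to the low-dose step only when every
gated parameter passes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerModelResult",
    "ProportionalityVerdict",
    "dose_normalize",
    "kruskal_wallis",
    "power_model_fit",
    "proportionality_gate",
    "proportionality_report",
]


@dataclass(frozen=True)
class PowerModelResult:
    """OLS fit of ln(value) = alpha + beta * ln(dose)."""

    parameter_name: str
    beta: float
    se_beta: float
    ci95: tuple[float, float]
    n_obs: int
    intercept: float = float("nan")

    def __post_init__(self) -> None:
        if not math.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not self.ci95[0] < self.ci95[1]:
            raise ValueError("CI must satisfy low < high")

    def contains_unity(self) -> bool:
        """Closed-interval check: the gate passes at the boundary."""
        return self.ci95[0] <= 1.0 <= self.ci95[1]


@dataclass
class ProportionalityVerdict:
    passes: bool
    reasons: dict[str, bool] = field(default_factory=dict)


def dose_normalize(value: float, dose: float):
    """Parameter value per mg of administered dose."""
    dose = float(dose)
    if dose <= 0:
        raise ValueError("dose must be positive")
    return np.asarray(value, dtype=float) / dose if np.ndim(value) else value / dose


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-squared p-value.

    The degenerate case where every value across all groups is identical is
    defined as H = 0, p = 1 (no evidence of any group difference).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def power_model_fit(
    observations: Sequence[tuple[float, float]] | np.ndarray,
    parameter_name: str = "parameter",
) -> PowerModelResult:
    """Fit the dose-proportionality power model by OLS on the log-log scale.

    ``observations`` are (dose mg, value) pairs; per-subject values are
    pooled across dose periods.  beta is the slope of ln(value) on
    ln(dose); the 95% CI is beta +/- t(0.975, n-2) * SE(beta).
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2 or obs.shape[0] < 3:
        raise ValueError("need >= 3 (dose, value) observations")
    doses, values = obs[:, 0], obs[:, 1]
    if np.any(doses <= 0) or np.any(values <= 0):
        raise ValueError("doses and values must be strictly positive")
    if np.unique(doses).size < 2:
        raise ValueError("need observations at >= 2 distinct doses")
    x = np.log(doses)
    y = np.log(values)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    beta = float(((x - xbar) * (y - ybar)).sum() / sxx)
    alpha = ybar - beta * xbar
    resid = y - (alpha + beta * x)
    dof = n - 2
    s2 = float(resid @ resid) / dof
    se = math.sqrt(s2 / sxx)
    tcrit = float(stats.t.ppf(0.975, dof))
    ci = (beta - tcrit * se, beta + tcrit * se)
    if not ci[0] < ci[1]:
        # zero residual variance: degenerate CI collapses onto beta
        eps = max(abs(beta), 1.0) * 1e-12
        ci = (beta - eps, beta + eps)
    return PowerModelResult(
        parameter_name=parameter_name,
        beta=beta,
        se_beta=se,
        ci95=ci,
        n_obs=n,
        intercept=float(alpha),
    )


def proportionality_gate(
    results: Sequence[PowerModelResult],
) -> ProportionalityVerdict:
    """Pass iff every parameter's 95% CI contains 1.0 (closed interval)."""
    results = list(results)
    if not results:
        raise ValueError("need at least one power-model result")
    reasons = {r.parameter_name: r.contains_unity() for r in results}
    return ProportionalityVerdict(passes=all(reasons.values()), reasons=reasons)


# ---------------------------------------------------------------------------
# Study-level report
# ---------------------------------------------------------------------------

#: Parameters gated per analyte, mirroring the escalation report layout:
#: Cmax and AUC_last for both analytes, plus AUC_HD for the metabolite.
GATED_PARAMETERS: Mapping[str, tuple[str, ...]] = {
    "parent": ("cmax", "auc_last"),
    "metabolite": ("cmax", "auc_last", "auc_hd"),
}


def proportionality_report(nca_table: pd.DataFrame) -> dict:
    """Dose-proportionality analysis of an escalation-study NCA table.

    Returns dose-normalized summaries with Kruskal-Wallis p-values
    (Cmax/dose and AUC_last/dose per analyte), the per-parameter power
    model results, and the overall gate verdict.
    """
    ok = nca_table[nca_table["error"].isna()] if "error" in nca_table else nca_table
    normalized_rows = []
    kw: dict[str, tuple[float, float]] = {}
    power: list[PowerModelResult] = []
    for analyte, params in GATED_PARAMETERS.items():
        sub = ok[ok["analyte"] == analyte]
        if sub.empty:
            continue
        for param in ("cmax", "auc_last"):
            groups = []
            for dose, g in sub.groupby("dose_mg"):
                vals = dose_normalize(g[param].dropna().to_numpy(), dose)
                groups.append(vals)
                normalized_rows.append(
                    {
                        "analyte": analyte,
                        "parameter": f"{param}/dose",
                        "dose_mg": dose,
                        "n": vals.size,
                        "mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
                    }
                )
            if len(groups) >= 2 and all(g.size for g in groups):
                kw[f"{analyte}:{param}/dose"] = kruskal_wallis(groups)
        for param in params:
            pairs = sub[["dose_mg", param]].dropna().to_numpy()
            if pairs.shape[0] >= 3 and np.unique(pairs[:, 0]).size >= 2:
                power.append(power_model_fit(pairs, f"{analyte}:{param}"))
    verdict = proportionality_gate(power) if power else ProportionalityVerdict(False, {})
    return {
        "dose_normalized": pd.DataFrame(normalized_rows),
        "kruskal_wallis": kw,
        "power_model": power,
        "verdict": verdict,
    }
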