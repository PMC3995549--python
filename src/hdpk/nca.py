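"""Non-compartmental analysis: Cmax/Tmax, linear-trapezoid AUC, terminal
slope, and the recovery-method dialytic clearance.

All exposures use the linear trapezoidal rule; AUC_last runs from dosing to
the last quantifiable time.  Oral clearance is CL/F = dose/AUC_last and
dialytic clearance follows the recovery method CL_HD = R/AUC_HD, where R is
the amount recovered in dialysate over the session and AUC_HD the plasma
AUC during the session.  Group statistics are reported as mean (SD), except
Tmax which is reported as median [min, max]; group clearances are means of
per-subject ratios, not ratios of group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .pkdata import (
    AllBelowLOQError,
    Analyte,
    ConcentrationProfile,
    DialysisWindow,
    Matrix,
    ProfileError,
    StudyConfig,
    censor_bloq,
)

__all__ = [
    "TerminalPhase",
    "NCAResult",
    "auc_linear_trapezoid",
    "cmax_tmax",
    "fit_lambda_z",
    "partial_auc_dialysis",
    "oral_clearance",
    "dialysis_clearance",
    "recovered_amount",
    "percent_excreted",
    "run_nca",
    "summarize_nca",
]

MG_TO_NG = 1e6
ML_TO_L = 1e-3


@dataclass(frozen=True)
class TerminalPhase:
    """Log-linear terminal phase: C(t) ~ exp(intercept - lambda_z * t)."""

    lambda_z: float  # 1/hr
    intercept: float  # ln(ng/mL)
    n_points: int
    adj_r2: float
    t_first: float
    t_last: float

    def __post_init__(self) -> None:
        if not self.lambda_z > 0:
            raise ValueError("lambda_z must be positive")
        if self.n_points < 3:
            raise ValueError("terminal fit needs at least 3 points")

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.lambda_z

    def conc_at(self, t) -> np.ndarray:
        return np.exp(self.intercept - self.lambda_z * np.asarray(t, dtype=float))


@dataclass
class NCAResult:
    """Per-subject, per-analyte non-compartmental parameters."""

    subject_id: str
    analyte: Analyte
    dose: float | None  # mg
    cmax: float  # ng/mL
    tmax: float  # hr
    auc_last: float  # ng*hr/mL
    t_last: float  # hr
    auc_hd: float | None = None  # ng*hr/mL, metabolite
    cl_f: float | None = None  # L/hr, parent
    recovered: float | None = None  # ng, dialysate integral
    cl_hd: float | None = None  # mL/hr, metabolite
    pct_excreted: float | None = None  # % of dose
    terminal: TerminalPhase | None = None
    error: str | None = None


# ---------------------------------------------------------------------------
# Elementary estimators
# ---------------------------------------------------------------------------

def _window_points(
    profile: ConcentrationProfile, t_start: float, t_end: float
) -> tuple[np.ndarray, np.ndarray]:
    """Quantifiable points inside [t_start, t_end] with interpolated
    boundary values when the boundaries are not sampled."""
    tq, cq = profile.quantifiable
    if tq.size < 2:
        raise ProfileError("need at least 2 quantifiable points for an AUC")
    if t_start < tq[0] or t_end > tq[-1]:
        raise ProfileError(
            f"AUC window [{t_start}, {t_end}] outside observed range "
            f"[{tq[0]}, {tq[-1]}]"
        )
    inner = (tq > t_start) & (tq < t_end)
    t = np.concatenate(([t_start], tq[inner], [t_end]))
    c = np.concatenate(
        (
            [np.interp(t_start, tq, cq)],
            cq[inner],
            [np.interp(t_end, tq, cq)],
        )
    )
    return t, c


def auc_linear_trapezoid(
    profile: ConcentrationProfile,
    t_start: float | None = None,
    t_end: float | None = None,
) -> float:
    """Linear-trapezoid AUC over [t_start, t_end] (ng*hr/mL).

    Defaults to the full quantifiable range (AUC_last when t_start is the
    dose time).  Non-sampled boundaries are linearly interpolated from the
    bracketing samples.
    """
    tq, _ = profile.quantifiable
    if tq.size < 2:
        raise ProfileError("need at least 2 quantifiable points for an AUC")
    if t_start is None:
        t_start = float(tq[0])
    if t_end is None:
        t_end = float(tq[-1])
    if t_end < t_start:
        raise ProfileError("t_end must be >= t_start")
    if t_end == t_start:
        return 0.0
    t, c = _window_points(profile, float(t_start), float(t_end))
    return float(np.trapezoid(c, t))


def cmax_tmax(profile: ConcentrationProfile) -> tuple[float, float]:
    """Maximum observed concentration and its time; ties -> earliest time."""
    tq, cq = profile.quantifiable
    if tq.size == 0:
        raise AllBelowLOQError(f"profile {profile.key} has no quantifiable data")
    i = int(np.argmax(cq))  # argmax returns the first maximum
    return float(cq[i]), float(tq[i])


def fit_lambda_z(
    profile: ConcentrationProfile, min_points: int = 3
) -> TerminalPhase:
    """Terminal log-linear slope by best-adjusted-R2 suffix selection.

    Candidate windows are every suffix of >= ``min_points`` quantifiable
    points ending at the last quantifiable sample and strictly after Tmax
    (the Tmax point itself is excluded, as is conventional for
    extravascular dosing).  Candidates with a non-negative slope are
    discarded; among the rest the window maximizing adjusted R2 wins
    (ties -> more points).
    """
    tq, cq = profile.quantifiable
    if tq.size == 0:
        raise AllBelowLOQError(f"profile {profile.key} has no quantifiable data")
    _, tmax = cmax_tmax(profile)
    mask = (tq > tmax) & (cq > 0)
    t_post, c_post = tq[mask], cq[mask]
    n_post = t_post.size
    if n_post < min_points:
        raise ProfileError(
            f"terminal fit needs >= {min_points} quantifiable points after "
            f"Tmax; got {n_post}"
        )
    logc = np.log(c_post)
    best: TerminalPhase | None = None
    for start in range(0, n_post - min_points + 1):
        t_w = t_post[start:]
        y_w = logc[start:]
        n = t_w.size
        slope, intercept = np.polyfit(t_w, y_w, 1)
        if slope >= 0:
            continue
        resid = y_w - (slope * t_w + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((y_w - y_w.mean()) ** 2).sum())
        if ss_tot == 0.0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        cand = TerminalPhase(
            lambda_z=-float(slope),
            intercept=float(intercept),
            n_points=n,
            adj_r2=float(adj),
            t_first=float(t_w[0]),
            t_last=float(t_w[-1]),
        )
        if best is None or cand.adj_r2 > best.adj_r2 + 1e-12:
            best = cand
    if best is None:
        raise ProfileError("no candidate terminal window with a negative slope")
    return best


def partial_auc_dialysis(
    profile: ConcentrationProfile, window: DialysisWindow
) -> float:
    """Plasma AUC over the dialysis session (AUC_HD), ng*hr/mL."""
    return auc_linear_trapezoid(profile, window.start, window.end)


def oral_clearance(dose: float, auc_last: float) -> float:
    """Apparent oral clearance CL/F = dose/AUC_last in L/hr.

    dose in mg, AUC in ng*hr/mL: dose*1e6/AUC gives mL/hr, scaled to L/hr.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    if auc_last <= 0:
        raise ValueError("AUC_last must be positive")
    return dose * MG_TO_NG / auc_last * ML_TO_L


def dialysis_clearance(recovered: float, auc_hd: float) -> float:
    """Recovery-method dialytic clearance CL_HD = R/AUC_HD in mL/hr."""
    if recovered < 0:
        raise ValueError("recovered amount must be non-negative")
    if auc_hd <= 0:
        raise ValueError("AUC_HD must be positive")
    return recovered / auc_hd


def recovered_amount(
    dialysate_profile: ConcentrationProfile, window: DialysisWindow
) -> float:
    """Amount recovered in dialysate over the session (ng).

    Trapezoidal integral of C_dialysate(t) * Q_d over the window, with the
    dialysate flow converted mL/min -> mL/hr.
    """
    if dialysate_profile.matrix is not Matrix.DIALYSATE:
        raise ProfileError("recovered_amount requires a dialysate profile")
    tq, _ = dialysate_profile.quantifiable
    if tq.size < 2:
        raise ProfileError("need at least 2 quantifiable dialysate points")
    auc_dial = auc_linear_trapezoid(
        dialysate_profile,
        max(window.start, float(tq[0])),
        min(window.end, float(tq[-1])),
    )
    return auc_dial * window.dialysate_flow * 60.0


def percent_excreted(recovered: float, dose: float) -> float:
    """Recovered amount as a percentage of the administered dose."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    if recovered < 0:
        raise ValueError("recovered amount must be non-negative")
    return 100.0 * recovered / (dose * MG_TO_NG)


# ---------------------------------------------------------------------------
# Study-level driver
# ---------------------------------------------------------------------------

def run_nca(
    profiles: Iterable[ConcentrationProfile],
    config: StudyConfig,
) -> pd.DataFrame:
    """NCA over a profile collection; one row per subject/analyte.

    Plasma profiles drive Cmax/Tmax/AUC_last; parent rows get CL/F,
    metabolite rows get AUC_HD over the configured dialysis window plus the
    recovery-method CL_HD and % excreted when a matching dialysate profile
    is present.  Per-profile failures become flagged rows (column
    ``error``), never aborts.
    """
    profiles = list(profiles)
    dialysate = {
        (p.subject_id, p.analyte): p
        for p in profiles
        if p.matrix is Matrix.DIALYSATE
    }
    rows: list[NCAResult] = []
    for p in profiles:
        if p.matrix is not Matrix.PLASMA:
            continue
        dose = p.dose.amount if p.dose is not None else None
        try:
            cp = censor_bloq(p)
            cmax, tmax = cmax_tmax(cp)
            tq, _ = cp.quantifiable
            auc_last = auc_linear_trapezoid(cp)
            res = NCAResult(
                subject_id=p.subject_id,
                analyte=p.analyte,
                dose=dose,
                cmax=cmax,
                tmax=tmax,
                auc_last=auc_last,
                t_last=float(tq[-1]),
            )
            try:
                res.terminal = fit_lambda_z(cp)
            except ProfileError:
                res.terminal = None
            if p.analyte is Analyte.PARENT and dose is not None:
                res.cl_f = oral_clearance(dose, auc_last)
            if p.analyte is Analyte.METABOLITE:
                w = config.dialysis
                if tq[0] <= w.start and tq[-1] >= w.end:
                    res.auc_hd = partial_auc_dialysis(cp, w)
                dial = dialysate.get((p.subject_id, p.analyte))
                if dial is not None and res.auc_hd is not None:
                    try:
                        cd = censor_bloq(dial)
                        res.recovered = recovered_amount(cd, w)
                        res.cl_hd = dialysis_clearance(res.recovered, res.auc_hd)
                        if dose is not None:
                            res.pct_excreted = percent_excreted(res.recovered, dose)
                    except ProfileError:
                        pass
            rows.append(res)
        except ProfileError as exc:
            rows.append(
                NCAResult(
                    subject_id=p.subject_id,
                    analyte=p.analyte,
                    dose=dose,
                    cmax=np.nan,
                    tmax=np.nan,
                    auc_last=np.nan,
                    t_last=np.nan,
                    error=str(exc),
                )
            )
    df = pd.DataFrame(
        {
            "subject": [r.subject_id for r in rows],
            "analyte": [r.analyte.value for r in rows],
            "dose_mg": [r.dose for r in rows],
            "cmax": [r.cmax for r in rows],
            "tmax": [r.tmax for r in rows],
            "auc_last": [r.auc_last for r in rows],
            "t_last": [r.t_last for r in rows],
            "auc_hd": [r.auc_hd for r in rows],
            "cl_f": [r.cl_f for r in rows],
            "recovered_ng": [r.recovered for r in rows],
            "cl_hd": [r.cl_hd for r in rows],
            "pct_excreted": [r.pct_excreted for r in rows],
            "lambda_z": [r.terminal.lambda_z if r.terminal else np.nan for r in rows],
            "lambda_z_adj_r2": [r.terminal.adj_r2 if r.terminal else np.nan for r in rows],
            "error": [r.error for r in rows],
        }
    )
    df.attrs["terminal_phases"] = {
        (r.subject_id, r.analyte.value): r.terminal for r in rows if r.terminal
    }
    return df


_SUMMARY_PARAMS = (
    "cmax", "auc_last", "auc_hd", "cl_f", "cl_hd", "pct_excreted",
)


def summarize_nca(nca_table: pd.DataFrame) -> pd.DataFrame:
    """Group summary by (analyte, dose): mean (SD) for exposures and
    clearances, median [min, max] for Tmax, as in standard NCA reporting."""
    ok = nca_table[nca_table["error"].isna()] if "error" in nca_table else nca_table
    out = []
    for (analyte, dose), g in ok.groupby(["analyte", "dose_mg"], dropna=False):
        row: dict[str, object] = {"analyte": analyte, "dose_mg": dose, "n": len(g)}
        for p in _SUMMARY_PARAMS:
            vals = g[p].dropna()
            row[f"{p}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{p}_sd"] = vals.std(ddof=1) if len(vals) > 1 else (0.0 if len(vals) == 1 else np.nan)
        tm = g["tmax"].dropna()
        row["tmax_median"] = tm.median() if len(tm) else np.nan
        row["tmax_min"] = tm.min() if len(tm) else np.nan
        row["tmax_max"] = tm.max() if len(tm) else np.nan
        out.append(row)
    return pd.DataFrame(out)
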