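"""Three-step dose-selection pipeline and simulated-vs-observed validation.

Step 1 runs NCA on the dose-escalation pilot and gates on dose
proportionality (every power-model 95% CI must contain 1.0).  Step 2 runs
NCA on the low-dose study, builds the predicted dose-exposure curve by
nonparametric superposition, inverts it at the target AUC_last and rounds
the exact dose up to a practical increment.  Step 3 superposes the
low-dose reference at the practical dose and scores the prediction against
the observed validation profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import doseprop, nca
from .pkdata import (
    AllBelowLOQError,
    Analyte,
    ConcentrationProfile,
    DoseEvent,
    Matrix,
    ProfileError,
    StudyConfig,
    censor_bloq,
)
from .superpose import (
    DoseExposureCurve,
    ExtendedReference,
    Regimen,
    invert_dose,
    predict_auc_vs_dose,
)

__all__ = [
    "DoseRecommendation",
    "ValidationMetrics",
    "ValidationReport",
    "PipelineReport",
    "round_dose",
    "validate_prediction",
    "run_pipeline",
]


@dataclass
class DoseRecommendation:
    exact_dose: float  # mg, curve inversion result
    practical_dose: float  # mg, rounded up to the increment
    target_auc: float  # ng*hr/mL
    curve: DoseExposureCurve

    def __post_init__(self) -> None:
        if self.practical_dose < self.exact_dose - 1e-9:
            raise ValueError("practical dose must not be below the exact dose")


@dataclass(frozen=True)
class ValidationMetrics:
    """Agreement between predicted and observed concentrations.

    AFE is the average fold error 10**mean(|log10(pred/obs)|) (>= 1,
    1 = perfect); pct_within_2fold counts pairs with pred/obs in [0.5, 2]
    (boundaries included).
    """

    n_pairs: int
    mape: float  # mean absolute percentage error, %
    afe: float  # average fold error
    frac_within_2fold: float
    pairs: pd.DataFrame | None = None


@dataclass
class ValidationReport:
    per_series: dict[tuple[str, str], ValidationMetrics] = field(default_factory=dict)
    notices: list[str] = field(default_factory=list)

    @property
    def overall_afe(self) -> float:
        """AFE pooled over every plasma pair (dialysate excluded: different
        matrix scale and sparse support)."""
        logs = []
        for (analyte, matrix), m in self.per_series.items():
            if matrix != Matrix.PLASMA.value or m.pairs is None:
                continue
            logs.append(np.abs(np.log10(m.pairs["simulated"] / m.pairs["observed"])))
        if not logs:
            return float("nan")
        return float(10 ** np.concatenate(logs).mean())


@dataclass
class PipelineReport:
    halted: bool
    step1: dict | None = None
    step2: dict | None = None
    step3: ValidationReport | None = None
    notices: list[str] = field(default_factory=list)

    @property
    def recommendation(self) -> DoseRecommendation | None:
        return self.step2["recommendation"] if self.step2 else None


def round_dose(exact: float, increment: float = 5.0, mode: str = "ceil") -> float:
    """Round a dose up to the next multiple of ``increment`` mg.

    Idempotent and monotone; an exact multiple is returned unchanged.
    """
    if exact <= 0:
        raise ValueError("exact dose must be positive")
    if increment <= 0:
        raise ValueError("increment must be positive")
    if mode != "ceil":
        raise ValueError(f"unsupported rounding mode: {mode!r}")
    k = math.ceil(exact / increment - 1e-9)
    return max(k, 1) * increment


def validate_prediction(
    observed: ConcentrationProfile,
    simulated: ConcentrationProfile,
    keep_pairs: bool = True,
) -> ValidationMetrics:
    """Score a simulated profile against observations.

    Pairs are formed at the observed quantifiable times with positive
    concentrations; the simulated profile is linearly interpolated there
    and must cover them.  A simulated zero against a positive observation
    counts as an out-of-2-fold failure and is excluded from the log-scale
    AFE.
    """
    t_obs, c_obs = observed.quantifiable
    pos = c_obs > 0
    t_obs, c_obs = t_obs[pos], c_obs[pos]
    if t_obs.size == 0:
        raise ProfileError("observed profile has no positive quantifiable points")
    tq_sim, cq_sim = simulated.quantifiable
    covered = (t_obs >= tq_sim[0]) & (t_obs <= tq_sim[-1])
    if not np.any(covered):
        raise ProfileError("no overlap between observed and simulated time ranges")
    t_obs, c_obs = t_obs[covered], c_obs[covered]
    c_sim = np.interp(t_obs, tq_sim, cq_sim)

    ratio = np.divide(c_sim, c_obs)
    within = (ratio >= 0.5) & (ratio <= 2.0)
    mape = float(np.mean(np.abs(c_sim - c_obs) / c_obs) * 100.0)
    posr = ratio > 0
    afe = float(10 ** np.mean(np.abs(np.log10(ratio[posr])))) if posr.any() else float("inf")
    pairs = (
        pd.DataFrame({"time_hr": t_obs, "observed": c_obs, "simulated": c_sim})
        if keep_pairs
        else None
    )
    return ValidationMetrics(
        n_pairs=int(t_obs.size),
        mape=mape,
        afe=afe,
        frac_within_2fold=float(within.mean()),
        pairs=pairs,
    )


# ---------------------------------------------------------------------------
# Pipeline helpers
# ---------------------------------------------------------------------------

def _mean_profile(
    profiles: Sequence[ConcentrationProfile],
    min_fraction: float = 0.5,
) -> ConcentrationProfile | None:
    """Across-subject mean of censored profiles on the common schedule.

    A time point is kept when at least ``min_fraction`` of the subjects
    contribute a value there.
    """
    censored = []
    for p in profiles:
        try:
            censored.append(censor_bloq(p))
        except AllBelowLOQError:
            continue
    if not censored:
        return None
    n = len(censored)
    values: dict[float, list[float]] = {}
    for p in censored:
        for t, c in zip(*p.quantifiable):
            values.setdefault(float(t), []).append(float(c))
    times = sorted(t for t, v in values.items() if len(v) >= max(1, min_fraction * n))
    if len(times) < 2:
        return None
    concs = [float(np.mean(values[t])) for t in times]
    ref = censored[0]
    return ConcentrationProfile(
        "group-mean", ref.analyte, ref.matrix, times, concs,
        dose=ref.dose, lloq=ref.lloq,
    )


def _predict_at_times(
    reference: ConcentrationProfile,
    terminal,
    regimen: Regimen,
    times: np.ndarray,
) -> np.ndarray:
    """Superposition evaluated exactly at ``times`` (no dense grid)."""
    ext = ExtendedReference(censor_bloq(reference), terminal)
    if reference.dose is None:
        raise ProfileError("reference profile carries no dose")
    d_ref = reference.dose.amount
    c = np.zeros_like(np.asarray(times, dtype=float))
    for e in regimen.events:
        lag = times - e.time
        active = lag >= 0
        c[active] += (e.amount / d_ref) * ext.conc(lag[active])
    return c


def _group_by_matrix(
    profiles: Iterable[ConcentrationProfile],
) -> dict[tuple[str, str], list[ConcentrationProfile]]:
    out: dict[tuple[str, str], list[ConcentrationProfile]] = {}
    for p in profiles:
        out.setdefault((p.analyte.value, p.matrix.value), []).append(p)
    return out


# ---------------------------------------------------------------------------
# The pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    pilot_data: Sequence[ConcentrationProfile],
    lowdose_data: Sequence[ConcentrationProfile],
    validation_data: Sequence[ConcentrationProfile] | None,
    config: StudyConfig,
    force_gate: bool = False,
    dose_grid: Sequence[float] | None = None,
    regimen_template: Regimen | None = None,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Run the three-step dose-selection method end to end.

    Step 1 halts the pipeline when the proportionality gate fails, unless
    ``force_gate`` is set (a small pilot can fail by chance).  An empty or
    None ``validation_data`` skips Step 3 with a notice.  The run is fully
    deterministic: identical inputs and config give identical reports.
    """
    report = PipelineReport(halted=False)

    # ---- Step 1: pilot escalation, linearity gate ---------------------
    pilot_nca = nca.run_nca(pilot_data, config)
    prop = doseprop.proportionality_report(pilot_nca)
    report.step1 = {
        "nca": pilot_nca,
        "summary": nca.summarize_nca(pilot_nca),
        **prop,
    }
    if not prop["verdict"].passes:
        if force_gate:
            report.notices.append(
                "proportionality gate FAILED but was overridden (--force-gate)"
            )
        else:
            report.halted = True
            report.notices.append(
                "proportionality gate failed; pipeline halted at Step 1"
            )
            _write_artifacts(report, outdir)
            return report

    # ---- Step 2: low-dose NCA, extrapolation, dose choice --------------
    lowdose_nca = nca.run_nca(lowdose_data, config)
    terminals = lowdose_nca.attrs.get("terminal_phases", {})
    met_profiles = [
        p for p in lowdose_data
        if p.analyte is Analyte.METABOLITE and p.matrix is Matrix.PLASMA
    ]
    if not met_profiles:
        raise ProfileError("low-dose dataset has no plasma metabolite profiles")
    ref_dose = next(
        (p.dose.amount for p in met_profiles if p.dose is not None), None
    )
    if ref_dose is None:
        raise ProfileError("low-dose profiles carry no dose_mg")
    t_end = float(max(config.sampling_times))
    if regimen_template is None:
        regimen_template = Regimen.single_dose(ref_dose, t_end=t_end)
    if dose_grid is None:
        dose_grid = np.arange(ref_dose, 150.0 + ref_dose / 2, ref_dose)

    per_subject_curves: list[DoseExposureCurve] = []
    for p in met_profiles:
        try:
            cp = censor_bloq(p)
            term = terminals.get((p.subject_id, Analyte.METABOLITE.value))
            per_subject_curves.append(
                predict_auc_vs_dose(cp, term, regimen_template, dose_grid)
            )
        except (ProfileError, ValueError) as exc:
            report.notices.append(
                f"step 2: subject {p.subject_id} excluded from extrapolation: {exc}"
            )
    if not per_subject_curves:
        raise ProfileError("no usable low-dose metabolite profile for extrapolation")
    grid = per_subject_curves[0].doses
    stacked = np.vstack([c.predicted_auc_last for c in per_subject_curves])
    mean_auc = stacked.mean(axis=0)
    se = (
        stacked.std(axis=0, ddof=1) / np.sqrt(stacked.shape[0])
        if stacked.shape[0] > 1
        else np.zeros_like(mean_auc)
    )
    mean_curve = DoseExposureCurve(
        grid, mean_auc,
        reference_dose=ref_dose,
        reference_auc=float(
            np.mean([c.reference_auc for c in per_subject_curves])
        ),
        se=se,
    )
    exact = invert_dose(mean_curve, config.target_auc)
    practical = round_dose(exact, config.rounding_increment)
    rec = DoseRecommendation(
        exact_dose=exact,
        practical_dose=practical,
        target_auc=config.target_auc,
        curve=mean_curve,
    )
    report.step2 = {
        "nca": lowdose_nca,
        "summary": nca.summarize_nca(lowdose_nca),
        "curve": mean_curve,
        "recommendation": rec,
        "n_subjects_extrapolated": stacked.shape[0],
    }

    # ---- Step 3: simulated-vs-observed validation ----------------------
    if not validation_data:
        report.notices.append("no validation data; Step 3 skipped")
        _write_artifacts(report, outdir)
        return report

    val_report = ValidationReport()
    observed_groups = _group_by_matrix(validation_data)
    lowdose_groups = _group_by_matrix(lowdose_data)
    val_regimen = regimen_template.scaled_to(practical)
    for key, obs_profiles in sorted(observed_groups.items()):
        mean_obs = _mean_profile(obs_profiles)
        if mean_obs is None:
            val_report.notices.append(
                f"{key}: too few quantifiable observations; series skipped"
            )
            continue
        refs = lowdose_groups.get(key, [])
        t_eval = mean_obs.times
        preds = []
        for p in refs:
            term = terminals.get((p.subject_id, p.analyte.value))
            try:
                preds.append(_predict_at_times(p, term, val_regimen, t_eval))
            except (ProfileError, AllBelowLOQError):
                continue
        if not preds:
            val_report.notices.append(
                f"{key}: no usable low-dose reference; series skipped"
            )
            continue
        mean_pred = np.mean(np.vstack(preds), axis=0)
        sim_profile = ConcentrationProfile(
            "predicted-mean", mean_obs.analyte, mean_obs.matrix,
            t_eval, mean_pred, dose=DoseEvent(practical), lloq=mean_obs.lloq,
        )
        try:
            val_report.per_series[key] = validate_prediction(mean_obs, sim_profile)
        except ProfileError as exc:
            val_report.notices.append(f"{key}: validation failed: {exc}")
    report.step3 = val_report
    _write_artifacts(report, outdir)
    return report


# ---------------------------------------------------------------------------
# Artifact output
# ---------------------------------------------------------------------------

def _write_artifacts(report: PipelineReport, outdir: str | Path | None) -> None:
    if outdir is None:
        return
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if report.step1:
        report.step1["nca"].to_csv(out / "pilot_nca.csv", index=False)
        report.step1["summary"].to_csv(out / "pilot_summary.csv", index=False)
        report.step1["dose_normalized"].to_csv(
            out / "pilot_dose_normalized.csv", index=False
        )
        pm = pd.DataFrame(
            {
                "parameter": [r.parameter_name for r in report.step1["power_model"]],
                "beta": [r.beta for r in report.step1["power_model"]],
                "se_beta": [r.se_beta for r in report.step1["power_model"]],
                "ci95_low": [r.ci95[0] for r in report.step1["power_model"]],
                "ci95_high": [r.ci95[1] for r in report.step1["power_model"]],
                "n_obs": [r.n_obs for r in report.step1["power_model"]],
                "contains_unity": [
                    r.contains_unity() for r in report.step1["power_model"]
                ],
            }
        )
        pm.to_csv(out / "pilot_power_model.csv", index=False)
    if report.step2:
        report.step2["nca"].to_csv(out / "lowdose_nca.csv", index=False)
        report.step2["summary"].to_csv(out / "lowdose_summary.csv", index=False)
        curve = report.step2["curve"]
        pd.DataFrame(
            {
                "dose_mg": curve.doses,
                "predicted_auc": curve.predicted_auc_last,
                "se": curve.se if curve.se is not None else np.nan,
            }
        ).to_csv(out / "dose_exposure_curve.csv", index=False)
        rec = report.step2["recommendation"]
        pd.DataFrame(
            [
                {
                    "exact_dose_mg": rec.exact_dose,
                    "practical_dose_mg": rec.practical_dose,
                    "target_auc": rec.target_auc,
                }
            ]
        ).to_csv(out / "recommendation.csv", index=False)
    if report.step3:
        rows = []
        for (analyte, matrix), m in sorted(report.step3.per_series.items()):
            rows.append(
                {
                    "analyte": analyte,
                    "matrix": matrix,
                    "n_pairs": m.n_pairs,
                    "mape_pct": m.mape,
                    "afe": m.afe,
                    "frac_within_2fold": m.frac_within_2fold,
                }
            )
        pd.DataFrame(rows).to_csv(out / "validation_metrics.csv", index=False)
    if report.notices:
        (out / "notices.txt").write_text("\n".join(report.notices) + "\n")
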