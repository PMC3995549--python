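"""Synthetic hemodialysis-patient PK study generator.

Ground-truth oracle for the rest of the package: a prodrug -> active
metabolite system with one-compartment disposition for both species,
first-order absorption, near-zero interdialytic metabolite clearance
(anuric patients), and an intermittent dialytic clearance switched on only
during the dialysis window:

    dA_gut/dt = -ka * A_gut
    dA_p/dt   =  ka * A_gut - E_p(C_p)
    dA_m/dt   =  fm * E_p(C_p) - (CL_m(t)/V_m) * A_m
    CL_m(t)   =  CL_m_inter + CL_hd * 1{t in dialysis window}

where E_p is the parent elimination rate: linear (CL_p/V_p)*A_p by
default, or Michaelis-Menten Vmax*C_p/(km + C_p) in the saturable variant
(Vmax chosen so the km -> infinity limit recovers the linear model).
Plasma concentrations are amounts/volumes; dialysate concentration during
the session is CL_hd * C_m / Q_d (flow-weighted recovery).  Amounts are
kept in ng, volumes in L, clearances in L/hr; concentrations are ng/mL.

Between-subject variability is log-normal on the structural parameters;
residual error is proportional (log-normal); observations below the LLOQ
are flagged BLOQ.  Everything is seeded and reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .pkdata import (
    Analyte,
    ConcentrationProfile,
    DIALYSATE_SAMPLING_TIMES,
    DialysisWindow,
    DoseEvent,
    Matrix,
    PAPER_SAMPLING_TIMES,
)

__all__ = [
    "SimParams",
    "SimScenario",
    "PKSolution",
    "solve_pk",
    "simulate_subject",
    "true_auc_last",
    "draw_population",
    "simulate_study",
    "saturable_variant",
]

MG_TO_NG = 1e6

#: Parameters receiving log-normal between-subject variability.
_IIV_PARAMS = ("ka", "V_p", "CL_p", "V_m", "CL_m_inter", "CL_hd")


@dataclass(frozen=True)
class SimParams:
    """Typical-subject PK parameters and variability settings.

    Defaults describe an anuric patient given the model prodrug: fast
    first-pass conversion (fm = 0.8 of absorbed drug reaches the
    circulation as metabolite), a metabolite that barely clears between
    sessions and is removed efficiently by high-flux dialysis.
    """

    ka: float = 1.5  # 1/hr, first-order absorption
    F: float = 1.0  # bioavailable fraction entering the gut compartment
    fm: float = 0.8  # fraction of parent elimination converted to metabolite
    V_p: float = 600.0  # L, apparent parent volume
    CL_p: float = 770.0  # L/hr, parent conversion/elimination clearance
    V_m: float = 15.0  # L, metabolite volume
    CL_m_inter: float = 0.03  # L/hr, interdialytic metabolite clearance
    CL_hd: float = 10.0  # L/hr, dialytic metabolite clearance (in-session)
    Q_d: float = 500.0  # mL/min, dialysate flow
    km: float | None = None  # ng/mL; None = linear parent elimination
    iiv_cv: float | Mapping[str, float] = 0.30  # log-normal CV per parameter
    residual_cv: float = 0.15  # proportional residual error CV
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("F", "fm"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("V_p", "V_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ka", "CL_p", "CL_m_inter", "CL_hd", "Q_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.km is not None and self.km <= 0:
            raise ValueError("km must be positive when set")

    def cv_for(self, name: str) -> float:
        if isinstance(self.iiv_cv, Mapping):
            return float(self.iiv_cv.get(name, 0.0))
        return float(self.iiv_cv)


@dataclass
class SimScenario:
    """A full virtual study: population, design and assay limits."""

    params: SimParams = field(default_factory=SimParams)
    doses: tuple[float, ...] = (2.5,)
    n_subjects: int = 10
    sampling_times: tuple[float, ...] = PAPER_SAMPLING_TIMES
    dialysate_times: tuple[float, ...] = DIALYSATE_SAMPLING_TIMES
    dialysis: DialysisWindow = field(default_factory=DialysisWindow)
    lloq_parent: float = 0.2
    lloq_metabolite: float = 2.0
    t_end: float = 72.0
    subject_prefix: str = "S"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        st = tuple(float(t) for t in self.sampling_times)
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("sampling times must be strictly increasing")
        self.sampling_times = st


def saturable_variant(params: SimParams, km: float) -> SimParams:
    """Michaelis-Menten parent elimination with Vmax = CL_p(as mL/hr) * km,
    so the km -> infinity limit recovers the linear model exactly."""
    if km <= 0:
        raise ValueError("km must be positive")
    return dataclasses.replace(params, km=km)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

class PKSolution:
    """Noiseless solution of the subject model, evaluable anywhere."""

    def __init__(
        self,
        params: SimParams,
        dose: float,
        dialysis: DialysisWindow | None,
        segments: list[tuple[float, float, object]],
        t_end: float,
    ) -> None:
        self.params = params
        self.dose = dose
        self.dialysis = dialysis
        self._segments = segments
        self.t_end = t_end

    def amounts(self, t) -> np.ndarray:
        """State [A_gut, A_p, A_m] in ng at times ``t`` (shape (3, n))."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros((3, t.size))
        if not self._segments:  # zero dose
            return out
        for (t0, t1, sol) in self._segments:
            m = (t >= t0) & (t <= t1)
            if np.any(m):
                out[:, m] = sol(t[m])
        return np.clip(out, 0.0, None)

    def parent_conc(self, t) -> np.ndarray:
        return self.amounts(t)[1] / (self.params.V_p * 1e3)

    def metabolite_conc(self, t) -> np.ndarray:
        return self.amounts(t)[2] / (self.params.V_m * 1e3)

    def dialysate_conc(self, t) -> np.ndarray:
        """Dialysate-side metabolite concentration; zero outside sessions."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        c = np.zeros_like(t)
        if self.dialysis is None or self.params.CL_hd == 0:
            return c
        w = self.dialysis
        inside = (t >= w.start) & (t <= w.end)
        q_d_ml_hr = self.params.Q_d * 60.0
        c[inside] = (
            self.params.CL_hd * 1e3 * self.metabolite_conc(t[inside]) / q_d_ml_hr
        )
        return c


def _rhs(params: SimParams, hd_active: bool):
    ka = params.ka
    fm = params.fm
    v_p_ml = params.V_p * 1e3
    cl_m = params.CL_m_inter + (params.CL_hd if hd_active else 0.0)
    k_m = cl_m / params.V_m
    if params.km is None:
        k_p = params.CL_p / params.V_p

        def rhs(t, y):
            a_gut, a_p, a_m = y
            absorbed = ka * a_gut
            elim = k_p * a_p
            return (-absorbed, absorbed - elim, fm * elim - k_m * a_m)

    else:
        vmax = params.CL_p * 1e3 * params.km  # ng/hr at saturation
        km = params.km

        def rhs(t, y):
            a_gut, a_p, a_m = y
            c_p = a_p / v_p_ml
            absorbed = ka * a_gut
            elim = vmax * c_p / (km + c_p)
            return (-absorbed, absorbed - elim, fm * elim - k_m * a_m)

    return rhs


def solve_pk(
    params: SimParams,
    dose: float,
    dialysis: DialysisWindow | None = None,
    t_end: float = 72.0,
    rtol: float = 1e-9,
) -> PKSolution:
    """Integrate the subject model for a single oral dose at t = 0.

    The dialytic clearance discontinuity is handled exactly by integrating
    piecewise between the window boundaries with a stiff-capable adaptive
    scheme (LSODA) and stitching the dense outputs together.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if dose == 0:
        return PKSolution(params, dose, dialysis, [], t_end)
    breaks = [0.0, t_end]
    if dialysis is not None:
        for b in (dialysis.start, dialysis.end):
            if 0.0 < b < t_end:
                breaks.append(b)
    breaks = sorted(set(breaks))
    dose_ng = dose * MG_TO_NG * params.F
    y0 = np.array([dose_ng, 0.0, 0.0])
    atol = dose_ng * 1e-12
    segments: list[tuple[float, float, object]] = []
    for t0, t1 in zip(breaks, breaks[1:]):
        mid = 0.5 * (t0 + t1)
        hd_active = dialysis is not None and dialysis.start <= mid < dialysis.end
        res = solve_ivp(
            _rhs(params, hd_active),
            (t0, t1),
            y0,
            method="LSODA",
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
        if not res.success:  # pragma: no cover - defensive
            raise RuntimeError(
                f"integration failed on [{t0}, {t1}] with params {params}: "
                f"{res.message}"
            )
        segments.append((t0, t1, res.sol))
        y0 = res.y[:, -1]
    return PKSolution(params, dose, dialysis, segments, t_end)


def true_auc_last(
    params: SimParams,
    dose: float,
    window: tuple[float, float] = (0.0, 72.0),
    dialysis: DialysisWindow | None = None,
    grid_step: float = 0.01,
) -> float:
    """Noiseless metabolite AUC over ``window`` on a fine grid (ng*hr/mL)."""
    if dialysis is None:
        dialysis = DialysisWindow()
    sol = solve_pk(params, dose, dialysis, t_end=max(window[1], 72.0))
    t = np.arange(window[0], window[1] + grid_step / 2, grid_step)
    return float(np.trapezoid(sol.metabolite_conc(t), t))


# ---------------------------------------------------------------------------
# Observation model
# ---------------------------------------------------------------------------

def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def simulate_subject(
    params: SimParams,
    dose: float,
    scenario: SimScenario,
    subject_id: str = "S01",
    rng: np.random.Generator | None = None,
    censor: bool = True,
) -> tuple[ConcentrationProfile, ConcentrationProfile, ConcentrationProfile]:
    """One subject's observed profiles at ``dose`` mg.

    Returns (plasma parent, plasma metabolite, dialysate metabolite).
    Proportional (log-normal) residual error is applied when
    ``params.residual_cv > 0`` and then values below the LLOQ are flagged
    BLOQ; with ``censor=False`` the raw noiseless or noisy values are
    returned unflagged (useful for oracle checks).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sol = solve_pk(params, dose, scenario.dialysis, t_end=scenario.t_end)
    t_plasma = np.asarray(scenario.sampling_times, dtype=float)
    t_dial = np.asarray(scenario.dialysate_times, dtype=float)

    dose_event = DoseEvent(dose) if dose > 0 else None

    def observe(conc: np.ndarray, lloq: float) -> tuple[np.ndarray, np.ndarray]:
        c = conc.copy()
        if params.residual_cv > 0:
            sigma = _lognormal_sigma(params.residual_cv)
            c = c * np.exp(rng.normal(0.0, sigma, size=c.shape))
        if not censor:
            return c, np.zeros(c.shape, dtype=bool)
        bloq = c < lloq
        c[bloq] = np.nan
        return c, bloq

    c_par, b_par = observe(sol.parent_conc(t_plasma), scenario.lloq_parent)
    c_met, b_met = observe(sol.metabolite_conc(t_plasma), scenario.lloq_metabolite)
    c_dia, b_dia = observe(sol.dialysate_conc(t_dial), scenario.lloq_metabolite)

    mk = lambda analyte, matrix, t, c, b, lloq: ConcentrationProfile(
        subject_id, analyte, matrix, t, c, b, dose=dose_event, lloq=lloq
    )
    return (
        mk(Analyte.PARENT, Matrix.PLASMA, t_plasma, c_par, b_par, scenario.lloq_parent),
        mk(Analyte.METABOLITE, Matrix.PLASMA, t_plasma, c_met, b_met, scenario.lloq_metabolite),
        mk(Analyte.METABOLITE, Matrix.DIALYSATE, t_dial, c_dia, b_dia, scenario.lloq_metabolite),
    )


def draw_population(
    params: SimParams, n: int, rng: np.random.Generator
) -> list[SimParams]:
    """Individualize the typical parameters with log-normal variability."""
    subjects = []
    for _ in range(n):
        overrides = {}
        for name in _IIV_PARAMS:
            cv = params.cv_for(name)
            base = getattr(params, name)
            if cv > 0 and base > 0:
                overrides[name] = base * float(
                    np.exp(rng.normal(0.0, _lognormal_sigma(cv)))
                )
        subjects.append(dataclasses.replace(params, **overrides))
    return subjects


def simulate_study(
    scenario: SimScenario,
    population: Sequence[SimParams] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full study; returns (dataset, ground-truth sidecar).

    The dataset is the long CSV dialect (one row per observation, with a
    ``dose_mg`` column).  The sidecar holds each virtual subject's drawn
    parameters and noiseless true AUC_last/Cmax per dose.  When the study
    crosses several doses (within-subject escalation) subject ids carry a
    dose suffix so profiles remain uniquely keyed.

    ``population`` allows reusing previously drawn subjects (e.g. the
    low-dose cohort returning for the validation period); otherwise
    ``n_subjects`` are drawn with the scenario seed.
    """
    if seed is None:
        seed = scenario.params.seed
    rng = np.random.default_rng(seed)
    if population is None:
        population = draw_population(scenario.params, scenario.n_subjects, rng)
    resid_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))

    frames = []
    truth_rows = []
    multi = len(scenario.doses) > 1
    for dose in scenario.doses:
        for i, p in enumerate(population, start=1):
            base_id = f"{scenario.subject_prefix}{i:02d}"
            sid = f"{base_id}-{dose:g}mg" if multi else base_id
            profs = simulate_subject(p, dose, scenario, sid, rng=resid_rng)
            frames.extend(prof.to_frame() for prof in profs)
            sol = solve_pk(p, dose, scenario.dialysis, t_end=scenario.t_end)
            tg = np.arange(0.0, scenario.t_end + 0.005, 0.01)
            cm = sol.metabolite_conc(tg)
            truth_rows.append(
                {
                    "subject": sid,
                    "base_subject": base_id,
                    "dose_mg": dose,
                    "true_auc_last": float(np.trapezoid(cm, tg)),
                    "true_cmax": float(cm.max()),
                    **{name: getattr(p, name) for name in _IIV_PARAMS},
                }
            )
    dataset = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return dataset, truth
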