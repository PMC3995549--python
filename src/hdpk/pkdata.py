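"""Domain types, units and tabular I/O for concentration-time data.

Conventions
-----------
* Time is hours since dosing; the dose is given at t = 0 (in the target
  study design, immediately after the end of a hemodialysis session), and
  the next dialysis session is expressed on the same clock (44-48 h by
  default).
* Concentrations are ng/mL throughout; doses are mg.  The mg -> ng factor
  of 1e6 is applied only inside clearance computations, never stored.
* A record flagged BLOQ (below the lower limit of quantification) carries
  no concentration; the applicable LLOQ lives on the profile.

The long CSV dialect has columns
``subject, analyte, matrix, time_hr, conc_ng_ml, bloq`` plus an optional
``dose_mg`` column carrying the administered dose for that profile.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Analyte",
    "Matrix",
    "DoseEvent",
    "DialysisWindow",
    "StudyConfig",
    "ConcentrationRecord",
    "ConcentrationProfile",
    "ProfileError",
    "DataFormatError",
    "AllBelowLOQError",
    "PAPER_SAMPLING_TIMES",
    "DIALYSATE_SAMPLING_TIMES",
    "load_profiles",
    "write_profiles",
    "profiles_to_frame",
    "censor_bloq",
    "interpolate_conc",
    "load_config",
    "save_config",
]

#: Plasma sampling schedule (hr): pre-dose plus the eleven post-dose draws;
#: 44 h = dialysis start, 48 h = dialysis end.
PAPER_SAMPLING_TIMES: tuple[float, ...] = (
    0.0, 1.0, 1.5, 2.0, 2.5, 3.0, 6.0, 12.0, 24.0, 44.0, 48.0, 72.0,
)

#: Dialysate collected hourly during the 4-h session.
DIALYSATE_SAMPLING_TIMES: tuple[float, ...] = (44.0, 45.0, 46.0, 47.0, 48.0)


class ProfileError(ValueError):
    """A concentration profile violates a structural precondition."""


class DataFormatError(ProfileError):
    """Malformed tabular input; message carries offending line numbers."""


class AllBelowLOQError(ProfileError):
    """Every record of a profile is BLOQ; the profile is unusable for NCA."""


class Analyte(str, enum.Enum):
    PARENT = "parent"
    METABOLITE = "metabolite"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Matrix(str, enum.Enum):
    PLASMA = "plasma"
    DIALYSATE = "dialysate"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose: ``amount`` mg administered at ``time`` hr."""

    amount: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if not (self.amount > 0 and math.isfinite(self.amount)):
            raise ValueError(f"dose amount must be positive, got {self.amount}")
        if not (self.time >= 0 and math.isfinite(self.time)):
            raise ValueError(f"dose time must be finite and >= 0, got {self.time}")


@dataclass(frozen=True)
class DialysisWindow:
    """One intermittent hemodialysis session on the dosing clock.

    Defaults reproduce the reference design: a 4-h high-flux session at
    44-48 h with dialysate flow 500 mL/min and blood flow 250 mL/min.
    """

    start: float = 44.0
    end: float = 48.0
    dialysate_flow: float = 500.0  # mL/min
    blood_flow: float = 250.0  # mL/min

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("dialysis window must have end > start")
        if self.dialysate_flow <= 0 or self.blood_flow <= 0:
            raise ValueError("dialysis flows must be positive")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t <= self.end


def _default_sampling() -> list[float]:
    return list(PAPER_SAMPLING_TIMES)


@dataclass
class StudyConfig:
    """Assay limits, dialysis schedule, exposure target and dosing policy."""

    lloq_parent: float = 0.2  # ng/mL
    lloq_metabolite: float = 2.0  # ng/mL
    dialysis: DialysisWindow = field(default_factory=DialysisWindow)
    target_auc: float = 60_000.0  # ng*hr/mL, metabolite AUC_last target
    sampling_times: list[float] = field(default_factory=_default_sampling)
    rounding_increment: float = 5.0  # mg

    def __post_init__(self) -> None:
        if self.lloq_parent <= 0 or self.lloq_metabolite <= 0:
            raise ValueError("LLOQs must be positive")
        if self.target_auc <= 0:
            raise ValueError("target_auc must be positive")
        if self.rounding_increment <= 0:
            raise ValueError("rounding_increment must be positive")

    def lloq_for(self, analyte: Analyte | str) -> float:
        if Analyte(analyte) is Analyte.PARENT:
            return self.lloq_parent
        return self.lloq_metabolite


@dataclass(frozen=True)
class ConcentrationRecord:
    """One observation; ``conc`` is None when the sample is BLOQ."""

    subject_id: str
    analyte: Analyte
    matrix: Matrix
    time: float
    conc: float | None
    bloq: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time) and self.time >= 0):
            raise ValueError(f"time must be finite and >= 0, got {self.time}")
        if self.bloq:
            if self.conc is not None:
                raise ValueError("BLOQ record must not carry a concentration")
        else:
            if self.conc is None or not math.isfinite(self.conc) or self.conc < 0:
                raise ValueError(f"concentration must be finite and >= 0, got {self.conc}")


class ConcentrationProfile:
    """A single subject/analyte/matrix concentration-time series.

    Internally stores times, concentrations (NaN where BLOQ) and the BLOQ
    mask as numpy arrays; times are strictly increasing.
    """

    def __init__(
        self,
        subject_id: str,
        analyte: Analyte | str,
        matrix: Matrix | str,
        times: Sequence[float],
        concs: Sequence[float | None],
        bloq: Sequence[bool] | None = None,
        dose: DoseEvent | None = None,
        lloq: float | None = None,
    ) -> None:
        self.subject_id = str(subject_id)
        self.analyte = Analyte(analyte)
        self.matrix = Matrix(matrix)
        t = np.asarray(times, dtype=float)
        c = np.array([np.nan if v is None else float(v) for v in concs], dtype=float)
        if bloq is None:
            b = np.isnan(c)
        else:
            b = np.asarray(bloq, dtype=bool)
        if t.ndim != 1 or t.shape != c.shape or t.shape != b.shape:
            raise ProfileError("times, concs and bloq must be 1-d and congruent")
        if t.size == 0:
            raise ProfileError("profile must contain at least one record")
        if not np.all(np.isfinite(t)) or np.any(t < 0):
            raise ProfileError("times must be finite and non-negative")
        if np.any(np.diff(t) <= 0):
            raise ProfileError("times must be strictly increasing")
        quant = ~b
        if np.any(~np.isfinite(c[quant])) or np.any(c[quant] < 0):
            raise ProfileError("quantifiable concentrations must be finite and >= 0")
        c = c.copy()
        c[b] = np.nan
        self.times = t
        self.concs = c
        self.bloq = b
        self.dose = dose
        self.lloq = lloq

    # -- basic views ----------------------------------------------------
    def __len__(self) -> int:
        return int(self.times.size)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ConcentrationProfile({self.subject_id!r}, {self.analyte.value}, "
            f"{self.matrix.value}, n={len(self)})"
        )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.subject_id, self.analyte.value, self.matrix.value)

    @property
    def records(self) -> list[ConcentrationRecord]:
        return [
            ConcentrationRecord(
                self.subject_id,
                self.analyte,
                self.matrix,
                float(t),
                None if bl else float(c),
                bool(bl),
            )
            for t, c, bl in zip(self.times, self.concs, self.bloq)
        ]

    @property
    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, concs) of the quantifiable records only."""
        m = ~self.bloq
        return self.times[m], self.concs[m]

    @property
    def n_quantifiable(self) -> int:
        return int((~self.bloq).sum())

    def with_values(
        self,
        times: np.ndarray | None = None,
        concs: np.ndarray | None = None,
        bloq: np.ndarray | None = None,
    ) -> "ConcentrationProfile":
        return ConcentrationProfile(
            self.subject_id,
            self.analyte,
            self.matrix,
            self.times if times is None else times,
            self.concs if concs is None else concs,
            self.bloq if bloq is None else bloq,
            dose=self.dose,
            lloq=self.lloq,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject": self.subject_id,
                "analyte": self.analyte.value,
                "matrix": self.matrix.value,
                "time_hr": self.times,
                "conc_ng_ml": self.concs,
                "bloq": self.bloq.astype(int),
            }
        )
        if self.dose is not None:
            df["dose_mg"] = self.dose.amount
        return df


# ---------------------------------------------------------------------------
# BLOQ handling and interpolation
# ---------------------------------------------------------------------------

def censor_bloq(profile: ConcentrationProfile, rule: str = "standard") -> ConcentrationProfile:
    """Apply the BLOQ convention ahead of NCA.

    Under the ``standard`` rule, BLOQ records before the first quantifiable
    concentration are set to zero (absorption has not started), while
    embedded and trailing BLOQ records are dropped so that AUC_last ends at
    the last quantifiable time.  Idempotent.

    Raises
    ------
    AllBelowLOQError
        If the profile has no quantifiable record at all.
    """
    if rule != "standard":
        raise ValueError(f"unknown BLOQ rule: {rule!r}")
    if profile.n_quantifiable == 0:
        raise AllBelowLOQError(
            f"profile {profile.key} has no quantifiable concentration"
        )
    first_q = int(np.argmax(~profile.bloq))
    keep = np.ones(len(profile), dtype=bool)
    concs = profile.concs.copy()
    for i in range(len(profile)):
        if not profile.bloq[i]:
            continue
        if i < first_q:
            concs[i] = 0.0  # leading BLOQ -> zero
        else:
            keep[i] = False  # embedded/trailing BLOQ -> excluded
    bloq = np.zeros(len(profile), dtype=bool)
    return profile.with_values(profile.times[keep], concs[keep], bloq[keep])


def interpolate_conc(
    profile: ConcentrationProfile, t: float, method: str = "linear"
) -> float:
    """Linearly interpolate the concentration at time ``t``.

    Works on the quantifiable records; ``t`` must lie within their observed
    range (extrapolation is the superposition module's job).  Exact at
    sample times.
    """
    if method != "linear":
        raise ValueError(f"unknown interpolation method: {method!r}")
    tq, cq = profile.quantifiable
    if tq.size == 0:
        raise AllBelowLOQError(f"profile {profile.key} has no quantifiable data")
    if not (tq[0] <= t <= tq[-1]):
        raise ProfileError(
            f"t={t} outside observed range [{tq[0]}, {tq[-1]}] for {profile.key}"
        )
    return float(np.interp(t, tq, cq))


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("subject", "analyte", "matrix", "time_hr", "conc_ng_ml", "bloq")


def profiles_to_frame(profiles: Iterable[ConcentrationProfile]) -> pd.DataFrame:
    frames = [p.to_frame() for p in profiles]
    if not frames:
        return pd.DataFrame(columns=list(_REQUIRED_COLUMNS))
    return pd.concat(frames, ignore_index=True)


def write_profiles(profiles: Iterable[ConcentrationProfile], path) -> None:
    """Write a profile collection to the long CSV dialect (UTF-8, header)."""
    profiles_to_frame(profiles).to_csv(path, index=False)


def load_profiles(
    path, config: StudyConfig | None = None
) -> list[ConcentrationProfile]:
    """Read the long CSV dialect into one profile per (subject, analyte, matrix).

    Malformed rows are rejected with their 1-based file line numbers
    (header is line 1).  Duplicate (subject, analyte, matrix, time) rows
    and negative times or concentrations are rejections, not warnings.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing required columns: {missing}")
    lines = df.index.to_numpy() + 2  # header occupies line 1

    problems: list[str] = []
    times = pd.to_numeric(df["time_hr"], errors="coerce")
    concs = pd.to_numeric(df["conc_ng_ml"], errors="coerce")
    bloq = df["bloq"].astype(str).str.strip().str.lower().isin(("1", "true", "yes"))

    bad_time = ~np.isfinite(times) | (times < 0)
    for ln in lines[bad_time]:
        problems.append(f"line {ln}: time_hr must be a finite non-negative number")
    bad_conc = (~bloq) & (~np.isfinite(concs) | (concs < 0))
    for ln in lines[bad_conc]:
        problems.append(f"line {ln}: conc_ng_ml must be a finite non-negative number")

    dup = df.assign(_t=times).duplicated(
        subset=["subject", "analyte", "matrix", "_t"], keep=False
    )
    # report every duplicate row after the first occurrence
    first = ~df.assign(_t=times).duplicated(
        subset=["subject", "analyte", "matrix", "_t"], keep="first"
    )
    for ln, sub, t in zip(lines[dup & ~first], df["subject"][dup & ~first], times[dup & ~first]):
        problems.append(f"line {ln}: duplicate time {t} for subject {sub!r}")
    if problems:
        raise DataFormatError("; ".join(problems))

    for col in ("analyte", "matrix"):
        valid = {a.value for a in (Analyte if col == "analyte" else Matrix)}
        bad = ~df[col].isin(valid)
        if bad.any():
            ln = lines[bad.to_numpy()][0]
            raise DataFormatError(
                f"line {ln}: {col} must be one of {sorted(valid)}, got {df[col][bad].iloc[0]!r}"
            )

    has_dose = "dose_mg" in df.columns
    out: list[ConcentrationProfile] = []
    for (subj, analyte, matrix), g in df.assign(_t=times, _c=concs, _b=bloq).groupby(
        ["subject", "analyte", "matrix"], sort=True
    ):
        g = g.sort_values("_t")
        dose = None
        if has_dose:
            d = pd.to_numeric(g["dose_mg"], errors="coerce").dropna().unique()
            if len(d) > 1:
                raise DataFormatError(
                    f"conflicting dose_mg values {sorted(d)} for subject {subj!r}"
                )
            if len(d) == 1:
                dose = DoseEvent(float(d[0]))
        lloq = config.lloq_for(analyte) if config is not None else None
        conc_vals = [None if b else float(c) for c, b in zip(g["_c"], g["_b"])]
        out.append(
            ConcentrationProfile(
                str(subj), analyte, matrix,
                g["_t"].to_numpy(), conc_vals, g["_b"].to_numpy(),
                dose=dose, lloq=lloq,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Config I/O (YAML)
# ---------------------------------------------------------------------------

def load_config(path) -> StudyConfig:
    """Load a StudyConfig from a YAML file mirroring its field names."""
    if hasattr(path, "read"):
        raw = yaml.safe_load(path)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    raw = dict(raw or {})
    if "dialysis" in raw and isinstance(raw["dialysis"], dict):
        raw["dialysis"] = DialysisWindow(**raw["dialysis"])
    return StudyConfig(**raw)


def save_config(config: StudyConfig, path) -> None:
    data = {
        "lloq_parent": config.lloq_parent,
        "lloq_metabolite": config.lloq_metabolite,
        "dialysis": {
            "start": config.dialysis.start,
            "end": config.dialysis.end,
            "dialysate_flow": config.dialysis.dialysate_flow,
            "blood_flow": config.dialysis.blood_flow,
        },
        "target_auc": config.target_auc,
        "sampling_times": list(config.sampling_times),
        "rounding_increment": config.rounding_increment,
    }
    if hasattr(path, "write"):
        yaml.safe_dump(data, path, sort_keys=False)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
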