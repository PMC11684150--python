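"""Patient-level record containers and their tidy-CSV representation.

A :class:`PatientRecord` is one subject: study tag (``TRIAL`` or ``RWE``),
treatment arm (``DVS`` or ``SOC``), a named baseline-covariate map, an
ordered visit sequence with the fistula-closure flag and the PDAI pain and
discharge items, and an optional censoring event (loss to follow-up,
proctectomy, or death).

Records round-trip through a pair of tidy DataFrames — one row per patient
for baseline, one row per visit — which is also the on-disk CSV format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import pandas as pd

STUDIES = ("TRIAL", "RWE")
ARMS = ("DVS", "SOC")
CENSOR_REASONS = ("lost", "proctectomy", "death")

#: Baseline covariate schema shared by both studies (one column per entry).
COVARIATE_SCHEMA = [
    "age",
    "gender",
    "ethnicity",
    "weight",
    "cd_duration",
    "smoking",
    "luminal_severity",
    "n_io",
    "n_eo",
    "prior_antibiotic",
    "prior_biologic",
    "prior_immunomod",
    "cdai",
    "pdai_pain_base",
    "pdai_discharge_base",
]

CATEGORICAL_COVARIATES = {
    "gender": ["male", "female"],
    "ethnicity": ["caucasian", "other"],
    "smoking": ["current", "former", "never"],
    "luminal_severity": ["mild_inactive", "moderate", "severe"],
    "n_io": [1, 2, 3],
    "n_eo": [1, 2, 3, 4],
    "prior_antibiotic": [0, 1],
    "prior_biologic": [0, 1],
    "prior_immunomod": [0, 1],
    "pdai_pain_base": [0, 1, 2, 3],
    "pdai_discharge_base": [0, 1, 2, 3],
}

NUMERIC_COVARIATES = ["age", "weight", "cd_duration", "cdai"]

#: Numeric covariates that are non-negative by construction.
NONNEGATIVE_COVARIATES = {"age", "weight", "cd_duration", "cdai"}


@dataclass
class Visit:
    """One assessment: week since treatment initiation plus the observables.

    ``eo_all_closed`` is the clinician-assessed closure of all external
    openings that were draining at baseline; ``None`` marks a visit at which
    the assessment was not completed. PDAI items are 0–3 or ``None``.
    """

    week: float
    eo_all_closed: Optional[bool]
    pdai_pain: Optional[int] = None
    pdai_discharge: Optional[int] = None

    def __post_init__(self) -> None:
        if self.week < 0:
            raise ValueError(f"visit week must be >= 0, got {self.week}")
        for name in ("pdai_pain", "pdai_discharge"):
            v = getattr(self, name)
            if v is not None and (int(v) != v or not 0 <= v <= 3):
                raise ValueError(f"{name} must be an integer in 0..3 or None, got {v}")


@dataclass
class PatientRecord:
    patient_id: str
    study: str
    arm: str
    covariates: dict = field(default_factory=dict)
    visits: list = field(default_factory=list)
    censor_event: Optional[tuple] = None  # (week, reason)
    has_post_index_assessment: bool = True
    latent: Optional[dict] = None  # exact latent event times, for oracles
    source: Optional[str] = None  # provenance tag after pooling

    def __post_init__(self) -> None:
        if self.study not in STUDIES:
            raise ValueError(f"study must be one of {STUDIES}, got {self.study!r}")
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        weeks = [v.week for v in self.visits]
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError(f"visit weeks must be strictly increasing: {weeks}")
        if self.censor_event is not None:
            cw, reason = self.censor_event
            if reason not in CENSOR_REASONS:
                raise ValueError(f"censor reason must be one of {CENSOR_REASONS}")
            if any(v.week > cw for v in self.visits):
                raise ValueError("visit after censoring event")

    def copy(self) -> "PatientRecord":
        return replace(
            self,
            covariates=dict(self.covariates),
            visits=[replace(v) for v in self.visits],
            latent=None if self.latent is None else dict(self.latent),
        )

    @property
    def last_observed_week(self) -> float:
        """End of observation: censoring week if present, else last visit."""
        if self.censor_event is not None:
            return self.censor_event[0]
        return self.visits[-1].week if self.visits else 0.0


def encode_covariates(cov: dict) -> dict:
    """Numeric design-features from a raw covariate map.

    Used both by the synthetic generator (true linear predictors) and by the
    fitting stage, so simulated effects and estimated effects live on the
    same feature scale. Continuous covariates are centred/scaled to keep
    coefficients O(1).
    """
    def _num(x, default):
        return default if x is None or (isinstance(x, float) and math.isnan(x)) else float(x)

    out = {
        "age_c": (_num(cov.get("age"), 38.0) - 38.0) / 10.0,
        "male": 1.0 if cov.get("gender") == "male" else 0.0,
        "caucasian": 1.0 if cov.get("ethnicity") == "caucasian" else 0.0,
        "weight_c": (_num(cov.get("weight"), 68.0) - 68.0) / 10.0,
        "cd_duration_c": (_num(cov.get("cd_duration"), 10.0) - 10.0) / 10.0,
        "smoker_current": 1.0 if cov.get("smoking") == "current" else 0.0,
        "luminal_active": 1.0 if cov.get("luminal_severity") in ("moderate", "severe") else 0.0,
        "n_eo_c": _num(cov.get("n_eo"), 1.5) - 1.5,
        "prior_antibiotic": _num(cov.get("prior_antibiotic"), 0.0),
        "prior_biologic": _num(cov.get("prior_biologic"), 0.0),
        "prior_immunomod": _num(cov.get("prior_immunomod"), 0.0),
        "cdai_c": (_num(cov.get("cdai"), 120.0) - 120.0) / 100.0,
    }
    return out


def records_to_frames(records: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (baseline, visits) tidy DataFrames for a record list."""
    base_rows, visit_rows = [], []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "study": r.study,
            "arm": r.arm,
            "has_post_index_assessment": r.has_post_index_assessment,
            "censor_week": r.censor_event[0] if r.censor_event else None,
            "censor_reason": r.censor_event[1] if r.censor_event else None,
            "source": r.source,
        }
        for k in COVARIATE_SCHEMA:
            row[k] = r.covariates.get(k)
        base_rows.append(row)
        for v in r.visits:
            visit_rows.append(
                {
                    "patient_id": r.patient_id,
                    "week": v.week,
                    "eo_all_closed": v.eo_all_closed,
                    "pdai_pain": v.pdai_pain,
                    "pdai_discharge": v.pdai_discharge,
                }
            )
    baseline = pd.DataFrame(base_rows)
    visits = pd.DataFrame(
        visit_rows,
        columns=["patient_id", "week", "eo_all_closed", "pdai_pain", "pdai_discharge"],
    )
    return baseline, visits


def frames_to_records(baseline: pd.DataFrame, visits: pd.DataFrame) -> list:
    """Inverse of :func:`records_to_frames` (latent times are not persisted)."""
    def _none(x):
        if x is None or (isinstance(x, float) and math.isnan(x)) or pd.isna(x):
            return None
        return x

    by_pid: dict = {pid: [] for pid in baseline["patient_id"]}
    for _, row in visits.iterrows():
        closed = _none(row["eo_all_closed"])
        if closed is not None:
            closed = bool(closed)
        pain = _none(row["pdai_pain"])
        disch = _none(row["pdai_discharge"])
        by_pid.setdefault(row["patient_id"], []).append(
            Visit(
                week=float(row["week"]),
                eo_all_closed=closed,
                pdai_pain=None if pain is None else int(pain),
                pdai_discharge=None if disch is None else int(disch),
            )
        )
    records = []
    for _, row in baseline.iterrows():
        cw = _none(row.get("censor_week"))
        censor = None if cw is None else (float(cw), row["censor_reason"])
        cov = {}
        for k in COVARIATE_SCHEMA:
            val = _none(row.get(k))
            if val is not None and k in CATEGORICAL_COVARIATES and not isinstance(val, str):
                levels = CATEGORICAL_COVARIATES[k]
                val = int(val) if not isinstance(levels[0], str) else val
            cov[k] = val
        vis = sorted(by_pid.get(row["patient_id"], []), key=lambda v: v.week)
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                study=row["study"],
                arm=row["arm"],
                covariates=cov,
                visits=vis,
                censor_event=censor,
                has_post_index_assessment=bool(row["has_post_index_assessment"]),
                source=_none(row.get("source")),
            )
        )
    return records
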