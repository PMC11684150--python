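"""Derivation of the four time-to-event outcomes from visit-level records.

Outcome definitions:

* ``CLIN_REMISSION`` — first visit at which all external openings that were
  draining at baseline are closed.
* ``CPC_REMISSION`` — first visit with closure AND PDAI pain = 0 AND PDAI
  discharge = 0 (clinical plus patient-centric remission).
* ``CLIN_RELAPSE_FROM_CPC`` — from the first CPC remission, first visit
  with loss of closure.
* ``CPC_RELAPSE_FROM_CPC`` — from the first CPC remission, first visit with
  loss of closure OR pain > 0 OR discharge > 0.

Time at risk for remission starts at treatment initiation (week 0); for
relapse it starts at the first CPC-remission visit (clock reset). Patients
without a qualifying event are censored at the earlier of their censoring
event (loss to follow-up, proctectomy, death) and their last visit; once a
patient has an event they contribute no further time at risk. Event and
censoring at the same week resolve to the event.

Samples are returned as a tidy DataFrame (one row per patient) carrying
``time`` (weeks), ``event`` (0/1) and the encoded covariate columns.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .records import encode_covariates

logger = logging.getLogger(__name__)

OUTCOMES = (
    "CLIN_REMISSION",
    "CPC_REMISSION",
    "CLIN_RELAPSE_FROM_CPC",
    "CPC_RELAPSE_FROM_CPC",
)

#: Relapse samples for patients whose CPC remission is their final
#: observation are censored at this positive epsilon (a sample per CPC
#: remission event is required, and times must be > 0).
_EPS_TIME = 1e-3


def _qualifies_remission(visit, kind: str, missing_pdai_counter: list) -> bool:
    if visit.eo_all_closed is None or not visit.eo_all_closed:
        return False
    if kind == "clinical":
        return True
    if visit.pdai_pain is None or visit.pdai_discharge is None:
        missing_pdai_counter[0] += 1
        return False
    return visit.pdai_pain == 0 and visit.pdai_discharge == 0


def _cpc_remission_week(r, counter):
    for v in r.visits:
        if _qualifies_remission(v, "cpc", counter):
            return v.week
    return None


def _sample_row(r, outcome, time, event):
    row = {
        "patient_id": r.patient_id,
        "outcome": outcome,
        "time": float(time),
        "event": int(event),
        "arm": r.arm,
        "study": r.study,
    }
    row.update(encode_covariates(r.covariates))
    return row


def derive_remission(records, kind: str = "cpc") -> pd.DataFrame:
    """Time to first clinical (``kind="clinical"``) or CPC remission."""
    if kind not in ("clinical", "cpc"):
        raise ValueError("kind must be 'clinical' or 'cpc'")
    outcome = "CLIN_REMISSION" if kind == "clinical" else "CPC_REMISSION"
    counter = [0]
    rows = []
    for r in records:
        informative = [v for v in r.visits if v.eo_all_closed is not None]
        if not informative:
            logger.warning("record %s has no completed assessment; excluded", r.patient_id)
            continue
        event_week = None
        for v in informative:
            if _qualifies_remission(v, kind, counter):
                event_week = v.week
                break
        if event_week is not None and event_week > 0:
            rows.append(_sample_row(r, outcome, event_week, 1))
        else:
            t = max(r.last_observed_week, _EPS_TIME)
            rows.append(_sample_row(r, outcome, t, 0))
    df = pd.DataFrame(rows)
    df.attrs["missing_pdai_at_qualifying_visit"] = counter[0]
    return df


def derive_relapse(records, kind: str = "cpc") -> pd.DataFrame:
    """Time from first CPC remission to clinical or CPC relapse.

    Only patients with an achieved CPC remission contribute; every such
    patient yields exactly one sample.
    """
    if kind not in ("clinical", "cpc"):
        raise ValueError("kind must be 'clinical' or 'cpc'")
    outcome = "CLIN_RELAPSE_FROM_CPC" if kind == "clinical" else "CPC_RELAPSE_FROM_CPC"
    counter = [0]
    rows = []
    for r in records:
        base_week = _cpc_remission_week(r, counter)
        if base_week is None:
            continue
        event_week = None
        for v in r.visits:
            if v.week <= base_week or v.eo_all_closed is None:
                continue
            lost_closure = not v.eo_all_closed
            if kind == "clinical":
                relapse = lost_closure
            else:
                pain = v.pdai_pain if v.pdai_pain is not None else 0
                disch = v.pdai_discharge if v.pdai_discharge is not None else 0
                if lost_closure is False and (v.pdai_pain is None or v.pdai_discharge is None):
                    counter[0] += 1
                relapse = lost_closure or pain > 0 or disch > 0
            if relapse:
                event_week = v.week
                break
        if event_week is not None:
            rows.append(_sample_row(r, outcome, event_week - base_week, 1))
        else:
            t = max(r.last_observed_week - base_week, _EPS_TIME)
            rows.append(_sample_row(r, outcome, t, 0))
    df = pd.DataFrame(rows)
    df.attrs["missing_pdai_at_qualifying_visit"] = counter[0]
    return df


def derive_all_outcomes(records) -> dict:
    """All four outcomes as ``{outcome_name: samples DataFrame}``."""
    return {
        "CLIN_REMISSION": derive_remission(records, "clinical"),
        "CPC_REMISSION": derive_remission(records, "cpc"),
        "CLIN_RELAPSE_FROM_CPC": derive_relapse(records, "clinical"),
        "CPC_RELAPSE_FROM_CPC": derive_relapse(records, "cpc"),
    }


def apply_lead_in(samples: pd.DataFrame, lead_in_weeks: float) -> pd.DataFrame:
    """Shift times for parametric fitting so [0, lead-in) is event-free.

    ``t' = max(t - lead_in, eps)``. Events recorded at or before the
    lead-in boundary contradict the lead-in assumption; they are kept (at
    ``eps``) but counted in ``df.attrs["lead_in_violations"]``.
    """
    if lead_in_weeks < 0:
        raise ValueError("lead_in_weeks must be >= 0")
    out = samples.copy()
    if lead_in_weeks == 0:
        out.attrs["lead_in_violations"] = 0
        out.attrs["lead_in_weeks"] = 0.0
        return out
    violations = int(((samples["time"] <= lead_in_weeks) & (samples["event"] == 1)).sum())
    if violations:
        logger.warning("%d event(s) at or before the %.3g-week lead-in", violations, lead_in_weeks)
    out["time"] = np.maximum(samples["time"] - lead_in_weeks, _EPS_TIME)
    out.attrs["lead_in_violations"] = violations
    out.attrs["lead_in_weeks"] = float(lead_in_weeks)
    return out
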