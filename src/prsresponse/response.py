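"""Responder / non-responder / unknown labels from longitudinal CGI records.

A subject counts as a responder when at least one response signal fires
(R1-R3) and every treatment-stability condition holds (R4-R6):

  R1  some CGI-S value is >= 2 points below an earlier CGI-S value, the two
      visits at least 30 days apart;
  R2  any CGI-S of 1 (normal, not at all ill);
  R3  any CGI-I <= 2 (much or very much improved);
  R4  treatment duration >= 90 days;
  R5  no antipsychotic or mood-stabilizer add-on within the window;
  R6  no dose increase after day 90 of treatment.

Non-response is assigned by three explicit rules: N1 — an add-on, a switch,
or a post-90-day dose increase within the window; N2 — discontinuation
attributed to inefficacy; N3 — adequate observation (>= 180 days spanned by
>= 2 CGI-S values, duration >= 90 days) with no response signal ever. Every
other record pattern is labelled unknown and excluded downstream.
Discontinuation for side effects is efficacy-uninformative and, alone, maps
to unknown.

Only records dated within [course start, course start + window_days] are
considered; treatment duration is the first discontinuation/switch date
(else the last observed record date) minus the course start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
UNKNOWN = "unknown"

ADDON_KINDS = {"addon_antipsychotic", "addon_mood_stabilizer"}
EVENT_KINDS = ADDON_KINDS | {"start", "dose_increase", "switch", "discontinuation"}

MIN_CGI_SPACING_DAYS = 30
MIN_TREATMENT_DAYS = 90
N3_MIN_SPAN_DAYS = 180


@dataclass
class ResponseLabel:
    subject_id: object
    label: str
    criteria: list  # satisfied rule ids driving the label
    window_days: int


def _to_days(dates, start) -> np.ndarray:
    """Day offsets from course start; accepts datetimes or plain numbers.

    Object-dtype columns (e.g. after concatenating tables) are routed by
    content: values coercible to numbers are day offsets, otherwise dates.
    """
    s = pd.Series(dates)
    num = pd.to_numeric(s, errors="coerce")
    if len(s) == 0 or not num.isna().any():
        return (num.astype(float) - float(pd.to_numeric(pd.Series([start])).iloc[0])).to_numpy()
    s = pd.to_datetime(s)
    return ((s - pd.to_datetime(start)).dt.days).to_numpy(dtype=float)


def classify_subject(
    cgi: pd.DataFrame,
    events: pd.DataFrame,
    window_days: int = 365,
    baseline_only: bool = False,
    subject_id=None,
) -> ResponseLabel:
    """Label one subject from their CGI observations and treatment events.

    ``cgi`` needs columns date/scale/value; ``events`` needs date/kind and
    optionally reason. Exactly one ``start`` event is required. With
    ``baseline_only`` the R1 comparison runs against the first CGI-S visit
    only rather than any earlier visit.
    """
    if len(cgi) and not cgi["value"].isin(range(1, 8)).all():
        raise ValueError(f"CGI values outside 1..7 for subject {subject_id!r}")
    bad_kind = set(events["kind"]) - EVENT_KINDS if len(events) else set()
    if bad_kind:
        raise ValueError(f"unknown event kinds {sorted(bad_kind)} for subject {subject_id!r}")
    starts = events[events["kind"] == "start"] if len(events) else events
    if len(starts) != 1:
        raise ValueError(
            f"subject {subject_id!r} needs exactly one course start event, found {len(starts)}"
        )
    start = starts["date"].iloc[0]

    ev = events.copy()
    ev["day"] = _to_days(ev["date"], start)
    if (ev["day"] < 0).any():
        raise ValueError(f"event before course start for subject {subject_id!r}")
    ev = ev[ev["day"] <= window_days]

    ob = cgi.copy()
    if len(ob):
        ob["day"] = _to_days(ob["date"], start)
        ob = ob[(ob["day"] >= 0) & (ob["day"] <= window_days)]
    else:
        ob = ob.assign(day=pd.Series(dtype=float))

    cgis = ob[ob["scale"] == "CGI-S"].sort_values("day")
    cgii = ob[ob["scale"] == "CGI-I"]

    # response signals
    r1 = False
    days = cgis["day"].to_numpy()
    vals = cgis["value"].to_numpy()
    earlier = [0] if (baseline_only and len(vals)) else range(len(vals))
    for i in earlier:
        later = (days >= days[i] + MIN_CGI_SPACING_DAYS) & (vals <= vals[i] - 2)
        if later.any():
            r1 = True
            break
    r2 = bool((cgis["value"] == 1).any())
    r3 = bool((cgii["value"] <= 2).any())

    disc = ev[ev["kind"].isin(("discontinuation", "switch"))]
    if len(disc):
        duration = float(disc["day"].min())
    else:
        last_days = [d for d in (ev["day"].max(), ob["day"].max() if len(ob) else np.nan) if not pd.isna(d)]
        duration = float(max(last_days)) if last_days else 0.0

    r4 = duration >= MIN_TREATMENT_DAYS
    addons = ev[ev["kind"].isin(ADDON_KINDS)]
    r5 = len(addons) == 0
    late_increase = ev[(ev["kind"] == "dose_increase") & (ev["day"] > MIN_TREATMENT_DAYS)]
    r6 = len(late_increase) == 0

    signal = r1 or r2 or r3
    satisfied = [r for r, ok in zip(("R1", "R2", "R3", "R4", "R5", "R6"), (r1, r2, r3, r4, r5, r6)) if ok]

    if signal and r4 and r5 and r6:
        return ResponseLabel(subject_id, RESPONDER, satisfied, window_days)

    # non-response rules
    switched = (ev["kind"] == "switch").any()
    if (not r5) or (not r6) or switched:
        return ResponseLabel(subject_id, NON_RESPONDER, ["N1"], window_days)
    reason = ev["reason"] if "reason" in ev.columns else pd.Series("", index=ev.index)
    inefficacy = ev[(ev["kind"] == "discontinuation") & (reason == "inefficacy")]
    if len(inefficacy):
        return ResponseLabel(subject_id, NON_RESPONDER, ["N2"], window_days)
    span = float(days.max() - days.min()) if len(days) >= 2 else 0.0
    if (not signal) and len(days) >= 2 and span >= N3_MIN_SPAN_DAYS and r4:
        return ResponseLabel(subject_id, NON_RESPONDER, ["N3"], window_days)
    return ResponseLabel(subject_id, UNKNOWN, satisfied, window_days)


def classify_response(
    cgi: pd.DataFrame,
    events: pd.DataFrame,
    window_days: int = 365,
    baseline_only: bool = False,
) -> pd.DataFrame:
    """Label every subject appearing in ``events``.

    Returns a DataFrame with subject_id, label and a ``criteria`` audit column
    (comma-joined satisfied rules / triggering non-response rule).
    """
    out = []
    for sid, sub_ev in events.groupby("subject_id", sort=True):
        sub_cgi = cgi[cgi["subject_id"] == sid]
        lab = classify_subject(
            sub_cgi, sub_ev, window_days=window_days, baseline_only=baseline_only, subject_id=sid
        )
        out.append({"subject_id": sid, "label": lab.label, "criteria": ",".join(lab.criteria)})
    return pd.DataFrame(out, columns=["subject_id", "label", "criteria"])
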