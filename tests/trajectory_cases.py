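"""Hand-built CGI/treatment trajectories with their designed labels.

Shared between the rule-engine unit tests and the acceptance suite. Days are
offsets from the course start (the classifier accepts numeric dates).
Treatment courses with no discontinuation/switch event carry a trailing
``discontinuation`` with reason ``other`` or a late observation so the
treatment duration is explicit.
"""

import pandas as pd

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
UNKNOWN = "unknown"

# name -> (cgi [(day, scale, value)], events [(day, kind, reason)], expected)
CASES = {
    # --- response signals -------------------------------------------------
    "r1_two_point_drop_45d": (
        [(0, "CGI-S", 5), (45, "CGI-S", 3)],
        [(0, "start", ""), (200, "discontinuation", "other")],
        RESPONDER,
    ),
    "r1_boundary_exactly_30d_2pt": (
        [(0, "CGI-S", 5), (30, "CGI-S", 3)],
        [(0, "start", ""), (200, "discontinuation", "other")],
        RESPONDER,
    ),
    "r1_from_mid_course_peak": (
        # worsens then improves: comparison against any earlier visit
        [(0, "CGI-S", 3), (30, "CGI-S", 5), (90, "CGI-S", 3)],
        [(0, "start", ""), (200, "discontinuation", "other")],
        RESPONDER,
    ),
    "r2_cgis_reaches_one": (
        [(0, "CGI-S", 2), (50, "CGI-S", 1)],
        [(0, "start", ""), (200, "discontinuation", "other")],
        RESPONDER,
    ),
    "r3_cgii_much_improved": (
        [(100, "CGI-I", 2)],
        [(0, "start", ""), (180, "discontinuation", "other")],
        RESPONDER,
    ),
    "r3_no_spacing_requirement": (
        [(10, "CGI-I", 1), (200, "CGI-S", 4)],
        [(0, "start", "")],
        RESPONDER,
    ),
    "responder_every_signal": (
        [(0, "CGI-S", 5), (100, "CGI-S", 1), (100, "CGI-I", 1)],
        [(0, "start", ""), (250, "discontinuation", "other")],
        RESPONDER,
    ),
    "r6_early_titration_allowed": (
        [(0, "CGI-S", 5), (60, "CGI-S", 3), (200, "CGI-S", 3)],
        [(0, "start", ""), (30, "dose_increase", "")],
        RESPONDER,
    ),
    "r6_day90_increase_not_after_90": (
        [(0, "CGI-S", 5), (60, "CGI-S", 3), (200, "CGI-S", 3)],
        [(0, "start", ""), (90, "dose_increase", "")],
        RESPONDER,
    ),
    # --- spacing / duration failures --------------------------------------
    "unknown_drop_only_20d_apart": (
        [(0, "CGI-S", 5), (20, "CGI-S", 3)],
        [(0, "start", ""), (200, "discontinuation", "other")],
        UNKNOWN,
    ),
    "unknown_signal_but_short_course": (
        [(0, "CGI-S", 5), (45, "CGI-S", 3)],
        [(0, "start", ""), (60, "discontinuation", "other")],
        UNKNOWN,
    ),
    # --- explicit non-response --------------------------------------------
    "n1_addon_mood_stabilizer_overrides_signal": (
        [(0, "CGI-S", 5), (45, "CGI-S", 3), (200, "CGI-S", 3)],
        [(0, "start", ""), (60, "addon_mood_stabilizer", "")],
        NON_RESPONDER,
    ),
    "n1_addon_antipsychotic": (
        [(0, "CGI-S", 4), (100, "CGI-S", 4)],
        [(0, "start", ""), (40, "addon_antipsychotic", "")],
        NON_RESPONDER,
    ),
    "n1_dose_increase_day150": (
        [(0, "CGI-S", 4), (45, "CGI-S", 4), (200, "CGI-S", 4)],
        [(0, "start", ""), (150, "dose_increase", "")],
        NON_RESPONDER,
    ),
    "n1_switch": (
        [(0, "CGI-S", 4), (100, "CGI-S", 4)],
        [(0, "start", ""), (120, "switch", "")],
        NON_RESPONDER,
    ),
    "n2_discontinued_for_inefficacy": (
        [(0, "CGI-S", 5)],
        [(0, "start", ""), (70, "discontinuation", "inefficacy")],
        NON_RESPONDER,
    ),
    "n2_short_observation_still_counts": (
        [],
        [(0, "start", ""), (30, "discontinuation", "inefficacy")],
        NON_RESPONDER,
    ),
    "n3_flat_full_year": (
        [(0, "CGI-S", 4), (100, "CGI-S", 4), (250, "CGI-S", 4), (365, "CGI-S", 4)],
        [(0, "start", "")],
        NON_RESPONDER,
    ),
    "n3_one_point_improvement_insufficient": (
        [(0, "CGI-S", 5), (60, "CGI-S", 4), (200, "CGI-S", 4)],
        [(0, "start", "")],
        NON_RESPONDER,
    ),
    # --- unknown-by-default ------------------------------------------------
    "unknown_side_effect_discontinuation": (
        [(0, "CGI-S", 5)],
        [(0, "start", ""), (70, "discontinuation", "side_effects")],
        UNKNOWN,
    ),
    "unknown_single_visit": (
        [(0, "CGI-S", 5)],
        [(0, "start", "")],
        UNKNOWN,
    ),
    "unknown_no_observations": (
        [],
        [(0, "start", "")],
        UNKNOWN,
    ),
    "unknown_flat_but_short_span": (
        [(0, "CGI-S", 4), (100, "CGI-S", 4)],
        [(0, "start", ""), (120, "discontinuation", "other")],
        UNKNOWN,
    ),
    # --- observation-window soundness --------------------------------------
    "window_excludes_late_addon": (
        [(0, "CGI-S", 5), (45, "CGI-S", 3), (200, "CGI-S", 3)],
        [(0, "start", ""), (400, "addon_antipsychotic", "")],
        RESPONDER,
    ),
    "window_excludes_late_cgi_signal": (
        [(0, "CGI-S", 5), (400, "CGI-S", 1)],
        [(0, "start", "")],
        UNKNOWN,
    ),
}


def build_frames(case_name, subject_id="X1"):
    cgi_rows, ev_rows, _ = CASES[case_name][0], CASES[case_name][1], CASES[case_name][2]
    cgi = pd.DataFrame(
        [{"subject_id": subject_id, "date": d, "scale": s, "value": v} for d, s, v in cgi_rows],
        columns=["subject_id", "date", "scale", "value"],
    )
    events = pd.DataFrame(
        [
            {"subject_id": subject_id, "date": d, "kind": k, "drug": "drug", "dose_mg_day": 10.0, "reason": r}
            for d, k, r in ev_rows
        ],
        columns=["subject_id", "date", "kind", "drug", "dose_mg_day", "reason"],
    )
    return cgi, events
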