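"""End-to-end glue: epoch counts -> session features -> models -> contrasts."""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from . import features as feat
from . import preprocess as prep
from .containers import EpochSeries


def extract_session_features(series: EpochSeries, session_age: float | None = None) -> dict:
    """Run the full feature-extraction chain on one 15 s session.

    Nonwear flagging, 60 s downsampling, rest-interval detection and
    valid-day accounting, then the actigraphy ART features.  Features whose
    sample-eligibility rule fails (fewer than five valid recording or sleep
    days, failed cosinor convergence) come back as None, mirroring how
    sessions drop out of the analytic samples.
    """
    flagged = prep.flag_nonwear(series)
    ds = prep.downsample_to_60s(flagged)
    intervals = prep.detect_sleep_intervals(ds)
    valid_rec, valid_sleep = prep.count_valid_days(ds, intervals)
    rar_ok, sleep_ok = prep.session_is_eligible(valid_rec, valid_sleep)

    row: dict = {
        "subject": series.subject,
        "session": series.session,
        "age": session_age,
        "valid_recording_days": valid_rec,
        "valid_sleep_days": valid_sleep,
        "rar_eligible": rar_ok,
        "sleep_eligible": sleep_ok,
        "alpha": None,
        "acrophase_h": None,
        "IS": None,
        "IV": None,
        "IV_out_of_range": False,
        "rest_length_h": None,
        "rest_midpoint_h": None,
        "rest_log_midpoint_sd": None,
    }
    if rar_ok:
        fit = feat.fit_extended_cosine(ds)
        if fit.usable:
            row["alpha"] = fit.alpha
            row["acrophase_h"] = fit.acrophase
        hourly = feat.hourly_means(ds)
        if len(hourly) >= 48:
            row["IS"] = feat.interdaily_stability(hourly)
            iv = feat.intradaily_variability(hourly)
            if iv is not None:
                row["IV"], row["IV_out_of_range"] = iv.value, iv.out_of_range
    if sleep_ok:
        summaries = feat.rest_interval_summaries(intervals)
        row["rest_length_h"] = summaries.mean_length_h
        row["rest_midpoint_h"] = summaries.midpoint_h
        row["rest_log_midpoint_sd"] = summaries.log_midpoint_sd
    return row


def extract_features(
    series_list: Iterable[EpochSeries],
    session_ages: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Session-feature table (one row per subject x session)."""
    rows = []
    for s in series_list:
        age = session_ages.get((s.subject, s.session)) if session_ages else None
        rows.append(extract_session_features(s, session_age=age))
    return pd.DataFrame(rows)


def self_report_features(selfreport: pd.DataFrame) -> pd.DataFrame:
    """Self-report ART features per visit: TST and the bed-to-wake midpoint."""
    out = selfreport[["subject", "age", "selfreport_tst_h"]].copy()
    out = out.rename(columns={"selfreport_tst_h": "sr_tst_h"})
    out["sr_midpoint_h"] = [
        feat.self_report_midpoint(b, w)
        for b, w in zip(
            selfreport["selfreport_bed_h"], selfreport["selfreport_wake_h"]
        )
    ]
    return out
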