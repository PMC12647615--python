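"""Event-related averaging and assembly of the long-format analysis table.

The hemodynamic response to a sentence sequence is the mean of the processed
series from 10 s after sequence onset (allowing the response to peak) to the
sequence offset, minus the mean of the 5 s immediately before onset. HbDiff
(HbO - HbR) window means are averaged over the two channels of each
prefrontal subregion -- or the single surviving channel when quality control
rejected one -- and only low-context, non-practice sequences enter the
statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocessing import QCReport
from .probe_io import ProbeMontage, SUBREGIONS
from .series import HbSeries

RESPONSE_DELAY_S = 10.0
BASELINE_S = 5.0


def epoch_response(hb: HbSeries, onset_s: float, offset_s: float) -> tuple[np.ndarray, np.ndarray]:
    """Window-mean HbO and HbR response per channel for one event.

    Mean over [onset+10 s, offset) minus the mean over [onset-5 s, onset).
    """
    if offset_s - onset_s <= RESPONSE_DELAY_S:
        raise ValueError("event shorter than the 10-s response delay")
    fs = hb.fs
    i0 = int(round((onset_s + RESPONSE_DELAY_S) * fs))
    i1 = int(round(offset_s * fs))
    b0 = int(round((onset_s - BASELINE_S) * fs))
    b1 = int(round(onset_s * fs))
    if b0 < 0 or i1 > hb.hbo.shape[0]:
        raise ValueError("event or baseline window outside the recording")
    hbo_mean = hb.hbo[i0:i1].mean(axis=0) - hb.hbo[b0:b1].mean(axis=0)
    hbr_mean = hb.hbr[i0:i1].mean(axis=0) - hb.hbr[b0:b1].mean(axis=0)
    return hbo_mean, hbr_mean


def hbdiff(hbo_mean, hbr_mean):
    """Cerebral oxygen exchange: HbO - HbR, exactly."""
    return np.asarray(hbo_mean) - np.asarray(hbr_mean)


def epoch_all_events(hb: HbSeries, events: pd.DataFrame) -> pd.DataFrame:
    """Per-event, per-channel window means; events too short for the analysis
    window (the decoys) are excluded and logged in the ``excluded`` attribute."""
    rows = []
    excluded = []
    for i, ev in events.iterrows():
        if ev.duration <= RESPONSE_DELAY_S:
            excluded.append(int(i))
            continue
        hbo_m, hbr_m = epoch_response(hb, float(ev.onset), float(ev.onset + ev.duration))
        for c in range(hb.n_channels):
            rows.append(
                {
                    "event": int(i),
                    "channel": c,
                    "condition": ev.condition,
                    "context": ev.context,
                    "block": int(ev.block),
                    "practice": bool(ev.practice),
                    "hbo_mean": float(hbo_m[c]),
                    "hbr_mean": float(hbr_m[c]),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["excluded_events"] = excluded
    return out


def aggregate_subregions(
    responses: pd.DataFrame, montage: ProbeMontage, qc: QCReport | None = None
) -> pd.DataFrame:
    """Mean response per event x subregion over surviving channels.

    Uses each subregion's two measurement channels, or the single channel that
    survived QC; rows where both channels were rejected are retained with a
    missing HbDiff so downstream models see the missingness explicitly. Only
    low-context, non-practice events are kept.
    """
    keep = (responses["context"] == "low") & (~responses["practice"])
    resp = responses[keep]
    valid = np.ones(montage.n_channels, dtype=bool) if qc is None else ~qc.rejected
    rows = []
    for event, grp in resp.groupby("event"):
        for sub in SUBREGIONS:
            ch_idx = [c.index for c in montage.subregion_channels(sub)]
            sub_rows = grp[grp["channel"].isin([c for c in ch_idx if valid[c]])]
            n_valid = len(sub_rows)
            if n_valid:
                hbo_m = float(sub_rows["hbo_mean"].mean())
                hbr_m = float(sub_rows["hbr_mean"].mean())
                hbd = hbo_m - hbr_m
            else:
                hbo_m = hbr_m = hbd = np.nan
            first = grp.iloc[0]
            rows.append(
                {
                    "event": int(event),
                    "condition": first["condition"],
                    "subregion": sub,
                    "hbo_mean": hbo_m,
                    "hbr_mean": hbr_m,
                    "hbdiff": hbd,
                    "n_valid_channels": n_valid,
                    "block": int(first["block"]),
                }
            )
    return pd.DataFrame(rows)


def condition_average(trial_responses: pd.DataFrame) -> pd.DataFrame:
    """Mean HbDiff per condition x subregion across low-context trials."""
    return (
        trial_responses.dropna(subset=["hbdiff"])
        .groupby(["condition", "subregion"], as_index=False)["hbdiff"]
        .mean()
    )


def build_trial_table(
    hb: HbSeries,
    events: pd.DataFrame,
    montage: ProbeMontage,
    qc: QCReport | None = None,
    behaviour: pd.DataFrame | None = None,
    participant: str = "P00",
    handedness: str = "right",
) -> pd.DataFrame:
    """Long-format table (one row per trial x subregion) for multilevel models."""
    responses = epoch_all_events(hb, events)
    table = aggregate_subregions(responses, montage, qc)
    table.insert(0, "participant", participant)
    table["handedness"] = handedness
    if behaviour is not None:
        beh = behaviour.set_index("event")[["effort", "correct"]]
        table = table.join(beh, on="event")
    return table


def normalized_timeseries(hb: HbSeries, montage: ProbeMontage) -> pd.DataFrame:
    """Z-scored HbDiff per subregion for plotting only (never statistics)."""
    z = (hb.hbdiff - hb.hbdiff.mean(axis=0)) / hb.hbdiff.std(axis=0)
    cols = {}
    for sub in SUBREGIONS:
        idx = [c.index for c in montage.subregion_channels(sub)]
        cols[sub] = z[:, idx].mean(axis=1)
    out = pd.DataFrame(cols)
    out.insert(0, "time_s", np.arange(len(out)) / hb.fs)
    return out
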