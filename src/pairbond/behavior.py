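"""Partner-preference behavior: event-log parsing and preference scoring.

The three-chamber test yields, per subject, the time spent on the
partner's side and the stranger's side over a 3-h trial plus the
side-by-side (huddling) contact durations with each stimulus animal.
The social preference ratio is (P − S)/(P + S) on the side times; it
lies in [−1, 1] and is undefined when both side times are zero.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from pairbond.photometry import BoutEvent
from pairbond.synthetic import PreferenceTrial

__all__ = [
    "PreferenceResult",
    "parse_event_log",
    "preference_ratio",
    "trials_to_frame",
]


@dataclass
class PreferenceResult:
    subject_id: str
    arm: str
    social_preference_ratio: float | None
    side_by_side_partner_s: float
    side_by_side_stranger_s: float
    undefined: bool = False


def parse_event_log(
    path: str | Path,
    codes: Mapping[str, str] | None = None,
    trial_span_s: float | None = None,
) -> list[BoutEvent]:
    """Parse a scored event log of (timestamp_s, code) rows into bouts.

    Each code toggles its behavior state: the first occurrence opens a
    bout, the next closes it. ``codes`` maps log codes to behavior
    labels (identity if omitted). States still open at the end of the
    log are closed at ``trial_span_s`` (or the last timestamp) with a
    warning. Timestamps must be non-decreasing; unknown codes raise.
    """
    rows: list[tuple[float, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for raw in reader:
            if not raw or raw[0].strip().lower() in ("timestamp_s", ""):
                continue
            rows.append((float(raw[0]), raw[1].strip()))

    last_t = float("-inf")
    open_at: dict[str, float] = {}
    bouts: list[BoutEvent] = []
    for t, code in rows:
        if t < last_t:
            raise ValueError(f"non-monotone timestamp {t} after {last_t}")
        last_t = t
        if codes is not None:
            if code not in codes:
                raise ValueError(f"unknown event code {code!r}")
            label = codes[code]
        else:
            label = code
        if label in open_at:
            start = open_at.pop(label)
            if t > start:
                bouts.append(BoutEvent(behavior_label=label, start_s=start, end_s=t))
        else:
            open_at[label] = t

    if open_at:
        close_at = trial_span_s if trial_span_s is not None else last_t
        for label, start in sorted(open_at.items()):
            if close_at > start:
                warnings.warn(
                    f"state {label!r} opened at {start} s never closed; "
                    f"closing at trial end {close_at} s",
                    stacklevel=2,
                )
                bouts.append(BoutEvent(behavior_label=label, start_s=start, end_s=close_at))
    bouts.sort(key=lambda b: (b.start_s, b.behavior_label))
    return bouts


def preference_ratio(trial: PreferenceTrial) -> PreferenceResult:
    """Social preference ratio (P − S)/(P + S) on chamber side times."""
    p, s = trial.time_partner_side_s, trial.time_stranger_side_s
    if p < 0 or s < 0:
        raise ValueError("side times must be non-negative")
    if p + s == 0:
        return PreferenceResult(
            subject_id=trial.subject_id,
            arm=trial.arm,
            social_preference_ratio=None,
            side_by_side_partner_s=trial.side_by_side_partner_s,
            side_by_side_stranger_s=trial.side_by_side_stranger_s,
            undefined=True,
        )
    return PreferenceResult(
        subject_id=trial.subject_id,
        arm=trial.arm,
        social_preference_ratio=(p - s) / (p + s),
        side_by_side_partner_s=trial.side_by_side_partner_s,
        side_by_side_stranger_s=trial.side_by_side_stranger_s,
    )


def trials_to_frame(trials: Sequence[PreferenceTrial]) -> pd.DataFrame:
    """Tidy per-subject table: side times, side-by-side times, ratio."""
    records = []
    for t in trials:
        r = preference_ratio(t)
        records.append(
            {
                "subject": t.subject_id,
                "arm": t.arm,
                "time_partner_side_s": t.time_partner_side_s,
                "time_stranger_side_s": t.time_stranger_side_s,
                "sbs_partner_s": t.side_by_side_partner_s,
                "sbs_stranger_s": t.side_by_side_stranger_s,
                "preference_ratio": r.social_preference_ratio,
            }
        )
    return pd.DataFrame.from_records(records)
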