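"""Event-aligned ΔF/F quantification for fiber-photometry sessions.

The analysis chain: a baseline F0 is taken as the mean fluorescence over
the 10 s immediately preceding stimulus exposure, ΔF/F = (F − F0)/F0 for
every sample of the epoch, bouts occurring within 4 s of the previous
retained bout are excluded, and each retained bout's response is the
mean ΔF/F over the fixed 4-s window following bout onset (regardless of
bout duration).

Conventions: time is continuous seconds; intervals are half-open
``[start, end)``; sample ``i`` of a trace covers time ``t0 + i/fs``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PhotometryTrace",
    "ExposureEpoch",
    "BoutEvent",
    "DffTrace",
    "PeriEventMatrix",
    "BoutResponse",
    "SessionSummary",
    "InvalidBaselineError",
    "compute_dff",
    "apply_refractory_exclusion",
    "extract_peri_event",
    "bout_response",
    "summarize_session",
]

RESPONSE_WINDOW_S: tuple[float, float] = (0.0, 4.0)
REFRACTORY_S: float = 4.0
BASELINE_WINDOW_S: float = 10.0


class InvalidBaselineError(ValueError):
    """Raised when F0 is non-positive or its window is truncated."""


@dataclass
class PhotometryTrace:
    """Raw fluorescence samples (arbitrary units) on a uniform grid."""

    samples: np.ndarray
    fs: float
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    def time(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class ExposureEpoch:
    """One stimulus-introduction epoch; onset anchors the F0 window."""

    stimulus_label: str
    stimulus_onset_s: float
    epoch_end_s: float


@dataclass(frozen=True)
class BoutEvent:
    """One annotated behavior bout, half-open interval [start, end)."""

    behavior_label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("bout must satisfy start < end")


@dataclass
class DffTrace:
    """Fractional fluorescence change over one epoch (0.5 = 50%)."""

    values: np.ndarray
    fs: float
    f0: float
    t0_s: float
    epoch: ExposureEpoch

    def time(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.fs


@dataclass
class PeriEventMatrix:
    """Bout-aligned ΔF/F: one row per included bout on a common grid."""

    values: np.ndarray  # (n_bouts, n_times)
    rel_time_s: np.ndarray
    fs: float
    bouts: list[BoutEvent]


@dataclass
class BoutResponse:
    bout_index: int
    bout: BoutEvent
    mean_dff: float
    included: bool
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if not self.included and not self.exclusion_reason:
            raise ValueError("excluded bout requires an exclusion_reason")


@dataclass
class SessionSummary:
    animal_id: str
    condition: str
    stimulus_means: dict[str, float] = field(default_factory=dict)
    n_bouts_included: dict[str, int] = field(default_factory=dict)
    missing_stimuli: list[str] = field(default_factory=list)


def compute_dff(trace: PhotometryTrace, epoch: ExposureEpoch) -> DffTrace:
    """ΔF/F = (F − F0)/F0 with F0 the mean over the 10 s before exposure.

    F0 is computed once per exposure epoch and reused for every bout in
    it. The returned trace spans from the start of the baseline window to
    the end of the epoch so that peri-event windows reaching before the
    first bouts stay inside it.
    """
    fs = trace.fs
    b0 = epoch.stimulus_onset_s - BASELINE_WINDOW_S
    i_b0 = int(round((b0 - trace.t0_s) * fs))
    i_on = int(round((epoch.stimulus_onset_s - trace.t0_s) * fs))
    i_end = min(int(round((epoch.epoch_end_s - trace.t0_s) * fs)) + 1, trace.samples.size)
    if i_b0 < 0 or i_on > trace.samples.size:
        raise InvalidBaselineError("baseline window [-10 s, 0) truncated by trace bounds")
    f0 = float(np.mean(trace.samples[i_b0:i_on]))
    if f0 <= 0:
        raise InvalidBaselineError(f"non-positive baseline F0 = {f0:.4g}")
    values = (trace.samples[i_b0:i_end] - f0) / f0
    return DffTrace(values=values, fs=fs, f0=f0, t0_s=trace.t0_s + i_b0 / fs, epoch=epoch)


def apply_refractory_exclusion(
    bouts: Sequence[BoutEvent],
    refractory_s: float = REFRACTORY_S,
    reference: str = "offset",
) -> list[tuple[BoutEvent, bool]]:
    """Exclude bouts that start too soon after the previous retained bout.

    A bout is excluded iff its onset minus the previous *included* bout's
    offset is < ``refractory_s``; the first bout is always included.
    ``reference="onset"`` switches to an onset-to-onset gap, an
    alternative reading of the exclusion rule kept behind this flag.
    """
    if reference not in ("offset", "onset"):
        raise ValueError("reference must be 'offset' or 'onset'")
    starts = [b.start_s for b in bouts]
    if starts != sorted(starts):
        raise ValueError("bouts must be sorted by start time")
    out: list[tuple[BoutEvent, bool]] = []
    last_ref: float | None = None
    for b in bouts:
        if last_ref is None or b.start_s - last_ref >= refractory_s:
            out.append((b, True))
            last_ref = b.end_s if reference == "offset" else b.start_s
        else:
            out.append((b, False))
    return out


def extract_peri_event(
    dff: DffTrace,
    bouts: Iterable[BoutEvent],
    pre_s: float = 10.0,
    post_s: float = 10.0,
) -> PeriEventMatrix:
    """Align ΔF/F to bout onsets on a common relative-time grid.

    Bouts whose window ``[onset − pre_s, onset + post_s]`` is not fully
    covered by the ΔF/F trace are dropped with a logged reason. An empty
    bout list yields a 0-row matrix.
    """
    fs = dff.fs
    n_cols = int(round((pre_s + post_s) * fs)) + 1
    rel = -pre_s + np.arange(n_cols) / fs
    t = dff.time()
    rows, kept = [], []
    for b in bouts:
        if b.start_s - pre_s < t[0] - 1e-9 or b.start_s + post_s > t[-1] + 1e-9:
            logger.info(
                "bout at %.2f s dropped: peri-event window outside trace", b.start_s
            )
            continue
        rows.append(np.interp(b.start_s + rel, t, dff.values))
        kept.append(b)
    values = np.vstack(rows) if rows else np.empty((0, n_cols))
    return PeriEventMatrix(values=values, rel_time_s=rel, fs=fs, bouts=kept)


def bout_response(
    peri: PeriEventMatrix, window_s: tuple[float, float] = RESPONSE_WINDOW_S
) -> list[BoutResponse]:
    """Mean ΔF/F per bout over the fixed response window [w0, w1).

    The window is the same for every bout regardless of bout duration.
    """
    w0, w1 = window_s
    if w0 < peri.rel_time_s[0] - 1e-9 or w1 > peri.rel_time_s[-1] + 1.0 / peri.fs + 1e-9:
        raise ValueError("response window outside the peri-event time span")
    mask = (peri.rel_time_s >= w0 - 1e-9) & (peri.rel_time_s < w1 - 1e-9)
    return [
        BoutResponse(bout_index=i, bout=b, mean_dff=float(np.mean(row[mask])), included=True)
        for i, (b, row) in enumerate(zip(peri.bouts, peri.values))
    ]


def summarize_session(
    responses_by_stimulus: dict[str, Sequence[BoutResponse]],
    animal_id: str = "",
    condition: str = "",
    expected_stimuli: Sequence[str] | None = None,
) -> SessionSummary:
    """Per-stimulus mean of included bout responses for one animal.

    A stimulus with no included bout is flagged missing, never silently
    reported as zero.
    """
    summary = SessionSummary(animal_id=animal_id, condition=condition)
    stimuli = list(responses_by_stimulus)
    if expected_stimuli is not None:
        stimuli = list(expected_stimuli)
    for stim in stimuli:
        included = [r.mean_dff for r in responses_by_stimulus.get(stim, []) if r.included]
        if not included:
            summary.missing_stimuli.append(stim)
            continue
        summary.stimulus_means[stim] = float(np.mean(included))
        summary.n_bouts_included[stim] = len(included)
    return summary
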