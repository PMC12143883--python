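"""Patch-clamp analysis: spontaneous PSC detection and summaries, evoked
E/I ratios, F–I curves with rheobase, and bath-application comparisons.

Spontaneous events are detected by matched filtering: the polarity-
corrected current trace is correlated with a unit-energy biexponential
template and local maxima of the detection statistic that exceed the
amplitude threshold (default 5 pA) are taken as events, with a 2-ms
minimum separation (overlapping candidates keep the larger peak).
Amplitudes are reported as absolute values so "larger" means the same
thing at −70 mV (inward) and 0 mV (outward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from pairbond.synthetic import Sweep, SweepSet, biexp_kernel

__all__ = [
    "DetectionParams",
    "DetectedEvent",
    "CellEventStats",
    "EIRatioResult",
    "FICurve",
    "PairedBathResult",
    "detect_events",
    "event_stats",
    "evoked_ei_ratio",
    "normalize_ei",
    "count_spikes",
    "fi_curve",
    "bath_da_compare",
]


@dataclass(frozen=True)
class DetectionParams:
    amp_threshold_pA: float = 5.0
    template_tau_rise_ms: float = 0.5
    template_tau_decay_ms: float = 5.0
    min_interval_ms: float = 2.0


@dataclass
class DetectedEvent:
    onset_s: float
    peak_amplitude_pA: float  # signed
    rise_10_90_ms: float
    decay_tau_ms: float
    polarity: str  # "inward" | "outward"


@dataclass
class CellEventStats:
    frequency_hz: float
    mean_amplitude_pA: float | None  # absolute; None when no events
    n_events: int


@dataclass
class EIRatioResult:
    cell_id: str
    group: str
    raw_ratio: float
    normalized_ratio: float | None = None


@dataclass
class FICurve:
    step_currents_pA: np.ndarray
    spike_counts: np.ndarray
    rheobase_pA: float | None  # None when no step elicits a spike


@dataclass
class PairedBathResult:
    cell_id: str
    group: str
    baseline: CellEventStats
    assessed: CellEventStats


def _polarity_for_holding(holding_mV: float | None) -> str:
    if holding_mV is None:
        raise ValueError("sweep lacks holding potential metadata")
    return "inward" if holding_mV < -10 else "outward"


def detect_events(
    sweep: Sweep,
    polarity: str,
    params: DetectionParams = DetectionParams(),
    t_start_s: float = 0.0,
    t_end_s: float | None = None,
) -> list[DetectedEvent]:
    """Detect spontaneous PSCs in one voltage-clamp sweep.

    ``polarity`` ("inward" or "outward") must match the holding
    potential recorded on the sweep; the optional window restricts
    detection to ``[t_start_s, t_end_s)``.
    """
    if sweep.units != "pA":
        raise ValueError(f"expected a current sweep in pA, got units {sweep.units!r}")
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    if sweep.holding_mV is not None and polarity != _polarity_for_holding(sweep.holding_mV):
        raise ValueError(
            f"polarity {polarity!r} inconsistent with holding {sweep.holding_mV} mV"
        )

    fs = sweep.fs
    sign = -1.0 if polarity == "inward" else 1.0
    x = sign * np.asarray(sweep.samples, dtype=float)  # events now positive
    i0 = int(round(t_start_s * fs))
    i1 = x.size if t_end_s is None else min(int(round(t_end_s * fs)), x.size)
    x = x[i0:i1]
    if x.size == 0:
        return []
    x = x - np.median(x)

    tau_r = params.template_tau_rise_ms / 1000.0
    tau_d = params.template_tau_decay_ms / 1000.0
    klen = max(int(np.ceil(6 * tau_d * fs)), 4)
    kt = np.arange(klen) / fs
    template = biexp_kernel(kt, tau_r, tau_d)  # unit peak
    unit = template / np.linalg.norm(template)

    # matched filter: response to a unit-peak event of amplitude A peaks at
    # A * ||template||, so the height threshold maps directly to pA
    stat = signal.fftconvolve(x, unit[::-1], mode="full")[klen - 1 :]
    height = params.amp_threshold_pA * np.linalg.norm(template) * 0.8
    distance = max(int(round(params.min_interval_ms / 1000.0 * fs)), 1)
    peaks, _ = signal.find_peaks(stat, height=height, distance=distance)

    tpk_rel = int(np.argmax(template))
    events: list[DetectedEvent] = []
    for p in peaks:
        # refine the actual peak in a window around the matched-filter hit
        lo = max(p, 0)
        hi = min(p + klen, x.size)
        if hi <= lo:
            continue
        seg = x[lo:hi]
        ipk = lo + int(np.argmax(seg))
        amp = float(x[ipk])
        if amp < params.amp_threshold_pA:
            continue
        onset_idx = p  # matched-filter alignment: template start
        rise, decay = _event_kinetics(x, ipk, amp, fs, klen)
        events.append(
            DetectedEvent(
                onset_s=(i0 + onset_idx) / fs,
                peak_amplitude_pA=sign * amp,
                rise_10_90_ms=rise,
                decay_tau_ms=decay,
                polarity=polarity,
            )
        )
    # de-duplicate events that resolved to overlapping peaks, keep larger
    events.sort(key=lambda e: e.onset_s)
    merged: list[DetectedEvent] = []
    min_sep = params.min_interval_ms / 1000.0
    for ev in events:
        if merged and ev.onset_s - merged[-1].onset_s < min_sep:
            if abs(ev.peak_amplitude_pA) > abs(merged[-1].peak_amplitude_pA):
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def _event_kinetics(
    x: np.ndarray, ipk: int, amp: float, fs: float, klen: int
) -> tuple[float, float]:
    """10–90% rise time and single-exponential decay constant (ms)."""
    # rise: walk back from the peak to the 10% and 90% crossings
    lo = max(ipk - klen, 0)
    seg = x[lo : ipk + 1]
    above10 = np.nonzero(seg >= 0.1 * amp)[0]
    above90 = np.nonzero(seg >= 0.9 * amp)[0]
    if above10.size and above90.size:
        rise = (above90[0] - above10[0]) / fs * 1000.0
    else:
        rise = float("nan")
    # decay: time to fall to 1/e of the peak
    tail = x[ipk : min(ipk + 3 * klen, x.size)]
    below = np.nonzero(tail <= amp / np.e)[0]
    decay = below[0] / fs * 1000.0 if below.size else float("nan")
    floor_ms = 1000.0 / fs
    rise = rise if np.isfinite(rise) and rise > floor_ms else floor_ms
    decay = decay if np.isfinite(decay) and decay > floor_ms else floor_ms
    return rise, decay


def event_stats(events: Sequence[DetectedEvent], duration_s: float) -> CellEventStats:
    """Frequency (events / recorded duration) and mean |amplitude|."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = len(events)
    amp = float(np.mean([abs(e.peak_amplitude_pA) for e in events])) if n else None
    return CellEventStats(frequency_hz=n / duration_s, mean_amplitude_pA=amp, n_events=n)


# ---------------------------------------------------------------------------
# evoked E/I


def _evoked_peak_amplitudes(trials: Sequence[Sweep], polarity: str) -> np.ndarray:
    """Baseline-subtracted per-trial peak amplitudes (absolute pA)."""
    sign = -1.0 if polarity == "inward" else 1.0
    amps = []
    for sw in trials:
        if sw.units != "pA":
            raise ValueError("evoked trials must be current sweeps in pA")
        stim = sw.stim_time_s if sw.stim_time_s is not None else 0.0
        i_stim = int(round(stim * sw.fs))
        baseline = float(np.mean(sw.samples[:i_stim])) if i_stim > 0 else 0.0
        resp = sign * (sw.samples[i_stim:] - baseline)
        amps.append(float(np.max(resp)))
    return np.asarray(amps)


def evoked_ei_ratio(
    epsc_trials: Sequence[Sweep],
    ipsc_trials: Sequence[Sweep],
    cell_id: str = "",
    group: str = "",
    n_required: int = 20,
) -> EIRatioResult:
    """E/I ratio: mean |evoked EPSC| / mean |evoked IPSC| for one cell.

    Per-trial peaks are measured on baseline-subtracted traces (baseline =
    pre-stimulus mean). The protocol contract is 20 trials per holding
    potential; a shortfall raises with the missing count.
    """
    for name, trials in (("EPSC", epsc_trials), ("IPSC", ipsc_trials)):
        if len(trials) != n_required:
            raise ValueError(
                f"{name} trials: expected {n_required}, got {len(trials)} "
                f"({n_required - len(trials):+d} missing)"
            )
    e = float(np.mean(_evoked_peak_amplitudes(epsc_trials, "inward")))
    i = float(np.mean(_evoked_peak_amplitudes(ipsc_trials, "outward")))
    if i <= 0:
        raise ValueError("mean IPSC amplitude is non-positive")
    return EIRatioResult(cell_id=cell_id, group=group, raw_ratio=e / i)


def normalize_ei(
    results: Sequence[EIRatioResult], control_group: str = "control"
) -> list[EIRatioResult]:
    """Divide every cell's raw ratio by the control-group mean raw ratio.

    By construction the control group's normalized ratios average 1.
    """
    control = [r.raw_ratio for r in results if r.group == control_group]
    if not control:
        raise ValueError(f"no cells in control group {control_group!r}")
    mean_control = float(np.mean(control))
    out = []
    for r in results:
        out.append(
            EIRatioResult(
                cell_id=r.cell_id,
                group=r.group,
                raw_ratio=r.raw_ratio,
                normalized_ratio=r.raw_ratio / mean_control,
            )
        )
    return out


# ---------------------------------------------------------------------------
# excitability


def count_spikes(
    voltage_sweep: Sweep, threshold_mV: float = 0.0, refractory_ms: float = 2.0
) -> int:
    """Count action potentials as upward threshold crossings (2-ms refractory)."""
    if voltage_sweep.units != "mV":
        raise ValueError("spike counting requires a voltage sweep in mV")
    v = np.asarray(voltage_sweep.samples)
    above = v >= threshold_mV
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    if crossings.size == 0:
        return 0
    min_gap = refractory_ms / 1000.0 * voltage_sweep.fs
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= min_gap:
            kept.append(c)
    return len(kept)


def fi_curve(step_sweeps: Sequence[Sweep], threshold_mV: float = 0.0) -> FICurve:
    """Spike count vs injected step current; rheobase = first spiking step."""
    steps = []
    for sw in step_sweeps:
        if sw.step_pA is None:
            raise ValueError("current-step sweep lacks step_pA metadata")
        steps.append(sw.step_pA)
    order = np.argsort(steps)
    steps_sorted = np.asarray(steps, dtype=float)[order]
    if np.any(np.diff(steps_sorted) <= 0):
        raise ValueError("duplicate step currents in sweep set")
    counts = np.asarray(
        [count_spikes(step_sweeps[i], threshold_mV) for i in order], dtype=int
    )
    spiking = np.nonzero(counts >= 1)[0]
    rheobase = float(steps_sorted[spiking[0]]) if spiking.size else None
    return FICurve(step_currents_pA=steps_sorted, spike_counts=counts, rheobase_pA=rheobase)


# ---------------------------------------------------------------------------
# bath application


def bath_da_compare(
    sweep_set: SweepSet,
    baseline_window_s: tuple[float, float] = (0.0, 600.0),
    assess_window_s: tuple[float, float] = (1800.0, 2400.0),
    params: DetectionParams = DetectionParams(),
) -> PairedBathResult:
    """Paired pre-drug vs drug event statistics for one bath-application cell.

    The protocol records 40 min continuously; the pre-drug window is the
    first 10 min and the assessed window the last 10 min. Windows must be
    disjoint and inside the recording.
    """
    if len(sweep_set.sweeps) != 1:
        raise ValueError("bath protocol expects one continuous sweep")
    sweep = sweep_set.sweeps[0]
    duration = sweep.samples.size / sweep.fs
    b0, b1 = baseline_window_s
    a0, a1 = assess_window_s
    if not (0 <= b0 < b1 <= a0 < a1):
        raise ValueError("windows must be ordered and non-overlapping")
    if a1 > duration + 1e-9:
        raise ValueError(
            f"recording ({duration:.0f} s) shorter than assessed window end ({a1:.0f} s)"
        )
    polarity = _polarity_for_holding(sweep.holding_mV)
    base = event_stats(
        detect_events(sweep, polarity, params, t_start_s=b0, t_end_s=b1), b1 - b0
    )
    assessed = event_stats(
        detect_events(sweep, polarity, params, t_start_s=a0, t_end_s=a1), a1 - a0
    )
    return PairedBathResult(
        cell_id=sweep_set.cell_id, group=sweep_set.group, baseline=base, assessed=assessed
    )
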