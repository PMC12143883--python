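"""Seeded synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (ΔF/F quantification, PSC
detection, F–I curves, preference scoring, statistics) is exercised on
data produced here, so each generator records the ground truth it
embedded: per-bout transient amplitudes, PSC event times, and
leaky-integrate-and-fire (LIF) spike counts.

Randomness is organised as one stream per generated object, derived from
``(seed, object-id)`` via :class:`numpy.random.SeedSequence`, so adding a
session to an experiment never perturbs previously generated sessions.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from pairbond.photometry import BoutEvent, ExposureEpoch, PhotometryTrace

__all__ = [
    "SimConfig",
    "LIFParams",
    "GroundTruth",
    "PhotometrySession",
    "Sweep",
    "SweepSet",
    "PreferenceTrial",
    "generate_photometry_session",
    "generate_sweep_set",
    "generate_preference_trial",
    "lif_spike_count_analytic",
    "biexp_kernel",
    "study_default_effects",
]

PHOTOMETRY_CONDITIONS = {
    f"{day}:{stim}"
    for day in ("day3", "day7")
    for stim in ("partner", "stranger", "object")
}
SWEEP_PROTOCOLS = ("spontaneous_vclamp", "evoked_vclamp", "current_steps", "bath_da")
PREFERENCE_ARMS = {
    f"{virus}:{drug}" for virus in ("Gq", "Gi", "mCherry") for drug in ("CNO", "saline")
}


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire membrane parameters.

    The LIF model is the simplest spiking model with a monotone F–I
    curve; it is used for current-step sweeps, not as a claim about
    medium-spiny-neuron biophysics.
    """

    R_MOhm: float = 200.0
    tau_m_ms: float = 10.0
    V_rest_mV: float = -80.0
    V_thresh_mV: float = -45.0
    V_reset_mV: float = -55.0


def _default_transient_amp() -> dict[str, float]:
    # ΔF/F peak amplitude per (cohabitation day, stimulus) label, emulating
    # a dopamine-sensor animal: partner > stranger only after bonding.
    return {
        "day3:partner": 0.02,
        "day3:stranger": 0.02,
        "day3:object": 0.0,
        "day7:partner": 0.04,
        "day7:stranger": 0.02,
        "day7:object": 0.0,
    }


@dataclass
class SimConfig:
    """Ground-truth parameters for all generators.

    Photometry amplitudes are fractional ΔF/F (0.04 = 4%); negative
    values emulate activity decreases (D2-type sessions). Rates are Hz,
    times seconds unless the name carries a unit suffix.
    """

    seed: int = 0
    fs_photometry: float = 20.0
    fs_ephys: float = 10_000.0
    session_length_s: float = 1800.0
    pre_stimulus_s: float = 30.0
    baseline_f: float = 1.0
    transient_amp: dict[str, float] = field(default_factory=_default_transient_amp)
    transient_amp_cv: float = 0.3
    transient_tau_rise_s: float = 0.2
    transient_tau_decay_s: float = 1.0
    noise_sd_photometry: float = 0.01
    drift_slope: float = 0.0
    bout_rate_hz: float = 0.05
    bout_duration_s: tuple[float, float] = (1.0, 3.0)
    psc_rate_hz: float = 2.0
    psc_amp_mean_pA: float = 20.0
    psc_amp_sd_pA: float = 5.0
    psc_tau_rise_ms: float = 0.5
    psc_tau_decay_ms: float = 5.0
    noise_sd_ephys_pA: float = 2.0
    noise_sd_ephys_mV: float = 0.3
    spontaneous_duration_s: float = 60.0
    evoked_epsc_amp_pA: float = 200.0
    evoked_ipsc_amp_pA: float = 150.0
    evoked_amp_cv: float = 0.1
    lif_params: LIFParams = field(default_factory=LIFParams)
    step_currents_pA: tuple[float, ...] = tuple(float(i) for i in range(0, 275, 25))
    step_duration_s: float = 1.0
    trial_span_s: float = 10_800.0
    side_time_base_s: float = 3_500.0
    side_time_sd_s: float = 600.0
    side_by_side_base_s: float = 1_200.0
    side_by_side_sd_s: float = 300.0
    group_effects: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs_photometry <= 0 or self.fs_ephys <= 0:
            raise ValueError("sampling rates must be positive")
        if self.transient_tau_decay_s <= self.transient_tau_rise_s:
            raise ValueError("transient tau_decay must exceed tau_rise")
        if self.psc_tau_decay_ms <= self.psc_tau_rise_ms:
            raise ValueError("psc tau_decay must exceed tau_rise")
        lo, hi = self.bout_duration_s
        if lo > hi or lo <= 0:
            raise ValueError("bout_duration_s must satisfy 0 < min <= max")

    def effect(self, group: str, measure: str) -> float:
        return self.group_effects.get((group, measure), 0.0)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """What a generator actually put into its traces."""

    true_bout_amplitudes: np.ndarray | None = None
    true_psc_times_s: list[np.ndarray] | None = None
    true_spike_counts: np.ndarray | None = None


@dataclass
class PhotometrySession:
    animal_id: str
    condition: str
    trace: PhotometryTrace
    epoch: ExposureEpoch
    bouts: list[BoutEvent]


@dataclass
class Sweep:
    samples: np.ndarray
    fs: float
    units: str  # "pA" or "mV"
    holding_mV: float | None = None
    step_pA: float | None = None
    stim_time_s: float | None = None


@dataclass
class SweepSet:
    cell_id: str
    group: str
    protocol: str
    sweeps: list[Sweep]


@dataclass
class PreferenceTrial:
    subject_id: str
    arm: str
    time_partner_side_s: float
    time_stranger_side_s: float
    side_by_side_partner_s: float
    side_by_side_stranger_s: float
    trial_span_s: float


def _rng(seed: int, *tags: object) -> np.random.Generator:
    """Independent stream keyed by (seed, tags); stable across runs."""
    digest = hashlib.sha256("/".join(str(t) for t in tags).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *words]))


def biexp_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalised to unit peak, zero for t<0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    # analytic peak of exp(-t/td) - exp(-t/tr)
    tpk = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-tpk / tau_decay) - np.exp(-tpk / tau_rise)
    return out / peak


def _poisson_times(rng: np.random.Generator, rate_hz: float, t0: float, t1: float) -> np.ndarray:
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


# ---------------------------------------------------------------------------
# photometry sessions


def generate_photometry_session(
    config: SimConfig, condition: str, animal_id: str = "A0"
) -> tuple[PhotometrySession, GroundTruth]:
    """Simulate one stimulus-exposure session for one animal.

    The fluorescence trace is ``baseline × (1 + Σ transients) + drift +
    noise``: transients are multiplicative on the baseline so that ΔF/F
    recovers their amplitude independent of detector gain. Sniffing bouts
    arrive as a Poisson process during the exposure; each bout locks a
    double-exponential transient to its onset with amplitude drawn around
    ``transient_amp[condition]`` (negative amplitudes emulate activity
    decreases). The epoch starts after ``pre_stimulus_s`` of baseline-only
    recording (≥10 s, the F0 window).
    """
    if condition not in PHOTOMETRY_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if config.pre_stimulus_s < 10.0:
        raise ValueError("pre_stimulus_s must be >= 10 s to hold the baseline window")
    if config.session_length_s <= 0:
        raise ValueError("session_length_s must be positive")

    rng = _rng(config.seed, "photometry", animal_id, condition)
    fs = config.fs_photometry
    onset = config.pre_stimulus_s
    total = onset + config.session_length_s
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs

    day, stimulus = condition.split(":")
    amp0 = config.transient_amp.get(condition, config.transient_amp.get(stimulus, 0.0))

    bout_starts = _poisson_times(rng, config.bout_rate_hz, onset, total - 5.0)
    lo, hi = config.bout_duration_s
    durations = rng.uniform(lo, hi, size=bout_starts.size)
    amps = amp0 + config.transient_amp_cv * abs(amp0) * rng.standard_normal(bout_starts.size)

    modulation = np.zeros(n)
    for start, a in zip(bout_starts, amps):
        i0 = int(np.ceil(start * fs))
        seg_t = t[i0:] - start
        # transient support truncated at 8 decay constants
        m = int(min(seg_t.size, np.ceil(8 * config.transient_tau_decay_s * fs)))
        modulation[i0 : i0 + m] += a * biexp_kernel(
            seg_t[:m], config.transient_tau_rise_s, config.transient_tau_decay_s
        )

    f = config.baseline_f * (1.0 + modulation)
    floor = 0.01 * config.baseline_f
    if np.any(f < floor):
        warnings.warn("fluorescence floored at 1% of baseline", stacklevel=2)
        f = np.maximum(f, floor)
    f = f + config.drift_slope * t
    if config.noise_sd_photometry > 0:
        f = f + config.noise_sd_photometry * rng.standard_normal(n)

    bouts = [
        BoutEvent(behavior_label="sniffing", start_s=float(s), end_s=float(s + d))
        for s, d in zip(bout_starts, durations)
    ]
    session = PhotometrySession(
        animal_id=animal_id,
        condition=condition,
        trace=PhotometryTrace(samples=f, fs=fs, t0_s=0.0),
        epoch=ExposureEpoch(stimulus_label=stimulus, stimulus_onset_s=onset, epoch_end_s=total),
        bouts=bouts,
    )
    return session, GroundTruth(true_bout_amplitudes=amps)


# ---------------------------------------------------------------------------
# patch-clamp sweep sets


def _psc_train(
    rng: np.random.Generator,
    config: SimConfig,
    duration_s: float,
    rate_hz: float,
    polarity: float,
) -> tuple[np.ndarray, np.ndarray]:
    """One voltage-clamp sweep of Poisson-timed biexponential PSCs + noise."""
    fs = config.fs_ephys
    n = int(round(duration_s * fs))
    trace = np.zeros(n)
    times = _poisson_times(rng, rate_hz, 0.0, duration_s - 0.05)
    tau_r = config.psc_tau_rise_ms / 1000.0
    tau_d = config.psc_tau_decay_ms / 1000.0
    klen = int(np.ceil(8 * tau_d * fs))
    kt = np.arange(klen) / fs
    kernel = biexp_kernel(kt, tau_r, tau_d)
    for t0 in times:
        amp = max(rng.normal(config.psc_amp_mean_pA, config.psc_amp_sd_pA), 1.0)
        i0 = int(np.round(t0 * fs))
        m = min(klen, n - i0)
        trace[i0 : i0 + m] += polarity * amp * kernel[:m]
    if config.noise_sd_ephys_pA > 0:
        trace += config.noise_sd_ephys_pA * rng.standard_normal(n)
    return trace, times


def _lif_sweep(
    rng: np.random.Generator, config: SimConfig, step_pA: float
) -> tuple[np.ndarray, int]:
    """Current-clamp LIF response to a 1-s step; returns (mV trace, spike count).

    The membrane equation is integrated exactly (exponential update with
    continuous-time threshold crossings inside each sample interval), so
    the spike count agrees with the closed-form interspike-interval
    prediction. Spikes are stereotyped 1-ms waveforms peaking at +30 mV
    pasted at each crossing, so a 0-mV upward-crossing counter recovers
    the count.
    """
    p = config.lif_params
    fs = config.fs_ephys
    dt_ms = 1000.0 / fs
    pre, post = 0.2, 0.3
    total = pre + config.step_duration_s + post
    n = int(round(total * fs))
    i_on = int(round(pre * fs))
    i_off = int(round((pre + config.step_duration_s) * fs))

    v = np.full(n, p.V_rest_mV)
    vm = p.V_rest_mV
    spikes = []
    for i in range(1, n):
        i_inj = step_pA if i_on <= i < i_off else 0.0
        v_inf = p.V_rest_mV + p.R_MOhm * i_inj / 1000.0  # MΩ·pA → mV via /1000
        remaining = dt_ms
        while True:
            if v_inf > p.V_thresh_mV and vm < p.V_thresh_mV:
                # exact time to threshold from vm under constant drive
                t_cross = p.tau_m_ms * np.log((v_inf - vm) / (v_inf - p.V_thresh_mV))
                if t_cross <= remaining:
                    spikes.append(i)
                    vm = p.V_reset_mV
                    remaining -= t_cross
                    continue
            vm = v_inf + (vm - v_inf) * np.exp(-remaining / p.tau_m_ms)
            break
        v[i] = vm

    spike_len = max(int(round(0.001 * fs)), 2)
    shape = 30.0 + np.zeros(spike_len)
    shape[spike_len // 2 :] = np.linspace(30.0, p.V_reset_mV, spike_len - spike_len // 2)
    for s in spikes:
        m = min(spike_len, n - s)
        v[s : s + m] = shape[:m]
    if config.noise_sd_ephys_mV > 0:
        v = v + config.noise_sd_ephys_mV * rng.standard_normal(n)
    return v, len(spikes)


def lif_spike_count_analytic(p: LIFParams, step_pA: float, duration_s: float) -> int:
    """Closed-form spike count of a noiseless LIF under a constant step."""
    v_inf = p.V_rest_mV + p.R_MOhm * step_pA / 1000.0
    if v_inf <= p.V_thresh_mV:
        return 0
    tau = p.tau_m_ms / 1000.0
    t_first = tau * np.log((v_inf - p.V_rest_mV) / (v_inf - p.V_thresh_mV))
    isi = tau * np.log((v_inf - p.V_reset_mV) / (v_inf - p.V_thresh_mV))
    if t_first > duration_s:
        return 0
    return 1 + int(np.floor((duration_s - t_first) / isi))


def _evoked_trial(
    rng: np.random.Generator, config: SimConfig, amp_pA: float, polarity: float
) -> Sweep:
    fs = config.fs_ephys
    duration, stim = 0.5, 0.1
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    amp = max(amp_pA * (1.0 + config.evoked_amp_cv * rng.standard_normal()), 1.0)
    trace = polarity * amp * biexp_kernel(t - stim, 0.001, 0.01)
    trace += -15.0  # holding-current offset; removed by baseline subtraction
    trace += config.noise_sd_ephys_pA * rng.standard_normal(n)
    return Sweep(samples=trace, fs=fs, units="pA", stim_time_s=stim)


def generate_sweep_set(
    config: SimConfig,
    protocol: str,
    group: str,
    cell_id: str = "C0",
    holding_mV: float = -70.0,
    n_sweeps: int = 1,
) -> tuple[SweepSet, GroundTruth]:
    """Simulate one cell's sweeps under one protocol.

    Protocols
    ---------
    ``spontaneous_vclamp``
        Poisson-timed biexponential PSCs plus Gaussian noise; polarity
        follows the holding potential (−70 mV → inward/negative events,
        0 mV → outward/positive).
    ``evoked_vclamp``
        Exactly 20 trials at each holding potential (−70 mV EPSC,
        0 mV IPSC), each a stimulus-locked PSC on a constant holding
        offset.
    ``current_steps``
        LIF voltage responses to 1000-ms steps over ``step_currents_pA``;
        true spike counts recorded in the ground truth.
    ``bath_da``
        A continuous 40-min voltage-clamp recording at −70 mV; after
        minute 10 the PSC rate and amplitude are scaled by the group's
        bath-drug effects, emulating dopamine wash-in.
    """
    if protocol not in SWEEP_PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    rng = _rng(config.seed, "ephys", protocol, group, cell_id)

    rate = config.psc_rate_hz * (1.0 + config.effect(group, "psc_rate"))
    amp_cfg = config.with_(
        psc_amp_mean_pA=config.psc_amp_mean_pA * (1.0 + config.effect(group, "psc_amp"))
    )

    if protocol == "spontaneous_vclamp":
        polarity = -1.0 if holding_mV < -10 else 1.0
        sweeps, truths = [], []
        for _ in range(n_sweeps):
            tr, times = _psc_train(rng, amp_cfg, config.spontaneous_duration_s, rate, polarity)
            sweeps.append(
                Sweep(samples=tr, fs=config.fs_ephys, units="pA", holding_mV=holding_mV)
            )
            truths.append(times)
        return (
            SweepSet(cell_id, group, protocol, sweeps),
            GroundTruth(true_psc_times_s=truths),
        )

    if protocol == "evoked_vclamp":
        epsc_amp = config.evoked_epsc_amp_pA * (1.0 + config.effect(group, "evoked_epsc"))
        ipsc_amp = config.evoked_ipsc_amp_pA * (1.0 + config.effect(group, "evoked_ipsc"))
        sweeps = []
        for _ in range(20):
            sw = _evoked_trial(rng, config, epsc_amp, polarity=-1.0)
            sw.holding_mV = -70.0
            sweeps.append(sw)
        for _ in range(20):
            sw = _evoked_trial(rng, config, ipsc_amp, polarity=+1.0)
            sw.holding_mV = 0.0
            sweeps.append(sw)
        return SweepSet(cell_id, group, protocol, sweeps), GroundTruth()

    if protocol == "current_steps":
        steps = np.asarray(config.step_currents_pA, dtype=float)
        sweeps, counts = [], []
        for step in steps:
            v, c = _lif_sweep(rng, config, step)
            sweeps.append(Sweep(samples=v, fs=config.fs_ephys, units="mV", step_pA=float(step)))
            counts.append(c)
        return (
            SweepSet(cell_id, group, protocol, sweeps),
            GroundTruth(true_spike_counts=np.asarray(counts)),
        )

    # bath_da: 40 min total; drug present from minute 10 onward
    total_s, drug_at_s = 2400.0, 600.0
    fs = config.fs_ephys
    n = int(round(total_s * fs))
    da_rate = rate * (1.0 + config.effect(group, "bath_da_rate"))
    da_amp_cfg = amp_cfg.with_(
        psc_amp_mean_pA=amp_cfg.psc_amp_mean_pA * (1.0 + config.effect(group, "bath_da_amp"))
    )
    pre, t_pre = _psc_train(rng, amp_cfg, drug_at_s, rate, -1.0)
    post, t_post = _psc_train(rng, da_amp_cfg, total_s - drug_at_s, da_rate, -1.0)
    trace = np.concatenate([pre, post])[:n]
    sweep = Sweep(samples=trace, fs=fs, units="pA", holding_mV=-70.0)
    times = np.concatenate([t_pre, t_post + drug_at_s])
    return (
        SweepSet(cell_id, group, protocol, [sweep]),
        GroundTruth(true_psc_times_s=[times]),
    )


# ---------------------------------------------------------------------------
# preference trials


def generate_preference_trial(
    config: SimConfig, arm: str, subject_id: str = "S0"
) -> PreferenceTrial:
    """Simulate one subject's three-chamber partner-preference trial (3 h).

    Side times and side-by-side durations are Gaussian around the
    configured bases, with ``group_effects[(arm, measure)]`` applied as
    fractional shifts (e.g. ``("Gi:CNO", "partner_side") = 0.3`` raises
    the partner-side mean by 30%). Times are clipped at zero and the two
    side times are rescaled if their sum would exceed the trial span.
    """
    if arm not in PREFERENCE_ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    rng = _rng(config.seed, "preference", arm, subject_id)

    def draw(base: float, sd: float, measure: str) -> float:
        return max(base * (1.0 + config.effect(arm, measure)) + sd * rng.standard_normal(), 0.0)

    p_side = draw(config.side_time_base_s, config.side_time_sd_s, "partner_side")
    s_side = draw(config.side_time_base_s, config.side_time_sd_s, "stranger_side")
    sbs_p = draw(config.side_by_side_base_s, config.side_by_side_sd_s, "sbs_partner")
    sbs_s = draw(config.side_by_side_base_s, config.side_by_side_sd_s, "sbs_stranger")

    if p_side + s_side > config.trial_span_s:
        scale = config.trial_span_s / (p_side + s_side)
        p_side, s_side = p_side * scale, s_side * scale
    sbs_p = min(sbs_p, p_side)
    sbs_s = min(sbs_s, s_side)
    return PreferenceTrial(
        subject_id=subject_id,
        arm=arm,
        time_partner_side_s=p_side,
        time_stranger_side_s=s_side,
        side_by_side_partner_s=sbs_p,
        side_by_side_stranger_s=sbs_s,
        trial_span_s=config.trial_span_s,
    )


def study_default_effects() -> dict[tuple[str, str], float]:
    """Effect structure emulating the chemogenetic behavioral findings:

    inhibiting the D2 projection (Gi + CNO) promotes partner preference,
    activating it (Gq + CNO) suppresses it, and the control virus
    (mCherry) is unaffected by the drug.
    """
    return {
        ("Gi:CNO", "partner_side"): 0.35,
        ("Gi:CNO", "sbs_partner"): 0.5,
        ("Gq:CNO", "partner_side"): -0.30,
        ("Gq:CNO", "sbs_partner"): -0.4,
    }
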