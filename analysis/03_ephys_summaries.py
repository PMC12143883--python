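"""Patch-clamp summaries: spontaneous PSCs, E/I ratio, excitability, bath DA.

Simulates a D2-type cell population in which cohabitation raises sEPSC
frequency and amplitude and the evoked E/I ratio, then recovers those
effects with the detection and summary chain and the study's tests
(pooled-variance unpaired t; normalization to the control E/I mean;
paired pre/post comparison for the dopamine bath).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pairbond import stats as st
from pairbond.ephys import (
    bath_da_compare,
    detect_events,
    event_stats,
    evoked_ei_ratio,
    fi_curve,
    normalize_ei,
)
from pairbond.synthetic import SimConfig, generate_sweep_set

RESULTS = Path("results")
RESULTS.mkdir(exist_ok=True)

EFFECTS = {
    ("cohabitation", "psc_rate"): 0.5,
    ("cohabitation", "psc_amp"): 0.2,
    ("cohabitation", "evoked_epsc"): 0.5,
    ("control", "bath_da_rate"): -0.5,  # DA suppresses sEPSCs in naive cells only
}
sim = SimConfig(seed=42, group_effects=EFFECTS, spontaneous_duration_s=60.0)
N_CELLS = 11  # cells per group for the spontaneous recordings

rows = []
for group in ("control", "cohabitation"):
    for i in range(N_CELLS):
        ss, _ = generate_sweep_set(sim, "spontaneous_vclamp", group, cell_id=f"{group}-{i}")
        events = detect_events(ss.sweeps[0], "inward")
        s = event_stats(events, sim.spontaneous_duration_s)
        rows.append(
            {
                "cell": f"{group}-{i}",
                "group": group,
                "sepsc_frequency_hz": s.frequency_hz,
                "sepsc_amplitude_pA": s.mean_amplitude_pA,
            }
        )
spont = pd.DataFrame(rows)
print("sEPSC summaries (group means):")
print(spont.groupby("group")[["sepsc_frequency_hz", "sepsc_amplitude_pA"]].mean().round(3))
t_freq = st.unpaired_t(
    spont.loc[spont.group == "control", "sepsc_frequency_hz"],
    spont.loc[spont.group == "cohabitation", "sepsc_frequency_hz"],
)
t_amp = st.unpaired_t(
    spont.loc[spont.group == "control", "sepsc_amplitude_pA"],
    spont.loc[spont.group == "cohabitation", "sepsc_amplitude_pA"],
)
print(f"frequency: {t_freq}")
print(f"amplitude: {t_amp}")

# evoked E/I, normalized to the control-group mean
ei = []
for group, n in (("control", 5), ("cohabitation", 7)):
    for i in range(n):
        ss, _ = generate_sweep_set(sim, "evoked_vclamp", group, cell_id=f"{group}-ei{i}")
        eps = [sw for sw in ss.sweeps if sw.holding_mV == -70.0]
        ips = [sw for sw in ss.sweeps if sw.holding_mV == 0.0]
        ei.append(evoked_ei_ratio(eps, ips, cell_id=f"{group}-ei{i}", group=group))
ei = normalize_ei(ei)
ei_frame = pd.DataFrame(
    {
        "cell": [r.cell_id for r in ei],
        "group": [r.group for r in ei],
        "ei_raw": [r.raw_ratio for r in ei],
        "ei_norm": [r.normalized_ratio for r in ei],
    }
)
print("\nE/I ratios (normalized to control mean):")
print(ei_frame.groupby("group")["ei_norm"].mean().round(3))
t_ei = st.unpaired_t(
    ei_frame.loc[ei_frame.group == "control", "ei_norm"],
    ei_frame.loc[ei_frame.group == "cohabitation", "ei_norm"],
)
print(f"E/I: {t_ei}")

# intrinsic excitability: F-I curve and rheobase
fi_rows = []
for group in ("control", "cohabitation"):
    for i in range(4):
        ss, _ = generate_sweep_set(sim, "current_steps", group, cell_id=f"{group}-fi{i}")
        curve = fi_curve(ss.sweeps)
        fi_rows.append({"cell": f"{group}-fi{i}", "group": group, "rheobase_pA": curve.rheobase_pA})
fi_frame = pd.DataFrame(fi_rows)
print("\nrheobase (pA):")
print(fi_frame.groupby("group")["rheobase_pA"].mean().round(1))

# bath DA: assessed (last 10 min) vs baseline (first 10 min) sEPSC frequency
bath_rows = []
bath_sim = sim.with_(fs_ephys=2000.0)
for group in ("control", "cohabitation"):
    for i in range(6):
        ss, _ = generate_sweep_set(bath_sim, "bath_da", group, cell_id=f"{group}-b{i}")
        r = bath_da_compare(ss)
        bath_rows.append(
            {
                "cell": r.cell_id,
                "group": group,
                "baseline_hz": r.baseline.frequency_hz,
                "da_hz": r.assessed.frequency_hz,
            }
        )
bath = pd.DataFrame(bath_rows)
print("\nbath DA sEPSC frequency (Hz):")
print(bath.groupby("group")[["baseline_hz", "da_hz"]].mean().round(3))
for group in ("control", "cohabitation"):
    sub = bath[bath.group == group]
    t = st.paired_t(sub["baseline_hz"], sub["da_hz"])
    print(f"paired baseline vs DA, {group}: {t}")

out = RESULTS / "ephys_summary.csv"
pd.concat(
    [
        spont.assign(measure="spontaneous"),
        ei_frame.assign(measure="ei"),
        fi_frame.assign(measure="fi"),
        bath.assign(measure="bath_da"),
    ]
).to_csv(out, index=False, float_format="%.4f")
print(f"\nwrote {out}")
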