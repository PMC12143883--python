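"""Generate one example of each synthetic data product and serialize it.

Writes an example photometry session (HDF5 trace + events CSV), an
evoked sweep set and a current-step sweep set (HDF5), and a preference
trial table (CSV), then prints what was embedded. Raw traces go under
scratch/ (bulky); tidy tables under results/.
"""

from pathlib import Path

from pairbond import io as pbio
from pairbond.behavior import trials_to_frame
from pairbond.synthetic import (
    SimConfig,
    generate_photometry_session,
    generate_preference_trial,
    generate_sweep_set,
    study_default_effects,
)

SCRATCH = Path("scratch/data")
RESULTS = Path("results")
SCRATCH.mkdir(parents=True, exist_ok=True)
RESULTS.mkdir(exist_ok=True)

sim = SimConfig(seed=42)

session, truth = generate_photometry_session(sim, "day7:partner", "A00")
pbio.save_session(SCRATCH / "example_session.h5", session)
print(
    f"photometry session: {len(session.bouts)} sniffing bouts over "
    f"{session.epoch.epoch_end_s - session.epoch.stimulus_onset_s:.0f} s exposure, "
    f"mean true transient amplitude {100 * truth.true_bout_amplitudes.mean():.2f}% dF/F"
)

evoked, _ = generate_sweep_set(sim, "evoked_vclamp", "control", "C00")
pbio.save_sweep_set(SCRATCH / "example_evoked.h5", evoked)
print(f"evoked sweep set: {len(evoked.sweeps)} trials (20 per holding potential)")

steps, gt = generate_sweep_set(sim, "current_steps", "control", "C00")
pbio.save_sweep_set(SCRATCH / "example_steps.h5", steps)
print(f"current steps: spike counts {gt.true_spike_counts.tolist()}")

trials = [
    generate_preference_trial(
        sim.with_(group_effects=study_default_effects()), arm, f"{arm}-S{i:02d}"
    )
    for arm in ("Gq:CNO", "Gi:CNO", "mCherry:saline")
    for i in range(4)
]
frame = trials_to_frame(trials)
frame.to_csv(RESULTS / "example_preference_trials.csv", index=False)
print(f"preference trials: {len(frame)} subjects -> {RESULTS / 'example_preference_trials.csv'}")
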