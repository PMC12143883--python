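# Methods

## Photometry model and ΔF/F chain

A session holds one stimulus-exposure epoch: ≥10 s of pre-stimulus
recording (default 30 s) followed by a 30-min exposure. The baseline F₀
is the mean fluorescence over the 10 s immediately preceding stimulus
onset and is computed once per epoch; ΔF/F = (F − F₀)/F₀ for every
sample of the epoch. No detrending or photobleaching correction is
applied beyond F₀ — the generator's linear drift term exists precisely
to probe sensitivity to that omission, and drift defaults to zero so the
default conditions are unconfounded.

Bout responses are the mean ΔF/F over a fixed 4-s window from bout
onset, regardless of bout duration. The refractory rule excludes a bout
whose onset falls within 4 s of the previous *included* bout's offset;
the first bout is always included, and excluded bouts do not reset the
clock. Two readings of "within 4 s of a prior bout" are defensible;
the offset-to-onset convention uses the full prior bout and is the
default, with the onset-to-onset alternative behind the ``reference``
flag of ``apply_refractory_exclusion``. Time is continuous seconds,
intervals half-open ``[start, end)``, sample ``i`` covering
``t0 + i/fs``.

A known consequence of the bout process: a follower bout that arrives
inside the previous bout's 4-s window contaminates that window with its
own transient even though the follower itself is excluded. This is a
property of the measurement, not a bug; ground-truth recovery tests
therefore isolate windows containing a single bout onset when checking
amplitude recovery.

## Synthetic-data generator

Fluorescence is ``baseline × (1 + Σ transients) + drift + noise``.
Transients are multiplicative on the baseline so ΔF/F recovers their
amplitude independent of detector gain. The transient kernel is a
difference of exponentials normalized to unit peak (rise 0.2 s, decay
1.0 s — indicator-like kinetics). Bouts are a Poisson process (default
0.05 Hz, durations uniform 1–3 s); per-bout amplitudes are Gaussian
around the condition's configured amplitude with CV 0.3. Default
amplitudes emulate a dopamine-sensor animal: day 3 partner = stranger
= 2% ΔF/F, day 7 partner 4% vs stranger 2%, object 0. Negative
amplitudes emulate D2-type activity decreases; fluorescence is floored
at 1% of baseline with a warning rather than going negative. Sampling is
20 Hz for photometry and 10 kHz for electrophysiology. Noise defaults
(1% of baseline per photometry sample; 2 pA per ephys sample against a
20 pA mean PSC) were chosen once so that the pipeline detects the
partner/stranger difference reliably at n = 7 animals while null
experiments stay calibrated; they are stated conditions, not tuning
knobs.

Randomness is one stream per generated object, derived from
``(seed, object-id)`` via ``SeedSequence``; adding sessions to an
experiment never perturbs existing ones, and a fixed seed reproduces
traces bit-for-bit.

Spontaneous PSCs are Poisson-timed biexponential events (rise 0.5 ms,
decay 5 ms; 2 Hz, 20 ± 5 pA) with polarity set by holding potential
(−70 mV inward/negative, 0 mV outward/positive). Evoked sets contain
exactly 20 trials per holding potential with a constant holding-current
offset so baseline subtraction is exercised. Current-step sweeps are
leaky integrate-and-fire (LIF) responses — R = 200 MΩ, τ_m = 10 ms,
V_rest = −80 mV, V_thresh = −45 mV, V_reset = −55 mV, giving a 175-pA
rheobase inside the 0–250 pA step range — integrated exactly
(exponential update with continuous-time threshold crossings inside each
sample), so spike counts match the closed-form interspike-interval
prediction; stereotyped 1-ms spike waveforms peaking at +30 mV are
pasted at crossings so a 0-mV crossing counter recovers the count. LIF
is the simplest model with a monotone F–I curve, not a claim about MSN
biophysics. The bath-application protocol records 40 min continuously
with the drug effect (a rate/amplitude scale factor per group) applied
from minute 10.

Preference trials draw side times and side-by-side durations as
truncated Gaussians around common bases (3500 s side time, 1200 s
side-by-side within a 10 800-s trial), with per-arm fractional effects;
the default study-like structure raises partner measures under Gi + CNO
and lowers them under Gq + CNO.

What the generator does **not** emulate: motion and hemodynamic
artifacts, photobleaching nonlinearity, sensor kinetics saturation,
correlated (non-Poisson) bout structure, PSC rise-time variability,
series-resistance errors, and within-trial behavioral dynamics. Passing
tests therefore demonstrate the correctness and calibration of the
analysis chain under the stated signal model, not robustness to every
artifact of real recordings.

## PSC event detection

The detector is a matched filter: the polarity-corrected,
median-centered trace is correlated with a unit-energy biexponential
template; local maxima of the detection statistic above the amplitude
threshold (default 5 pA, mapped through the template norm with a 0.8
safety factor for shape mismatch) and separated by ≥2 ms are events;
overlapping candidates keep the larger peak. Onsets come from the
matched-filter alignment; peak amplitude is read from the trace, rise
time as the 10–90% span, decay as the 1/e fall time, floored at one
sample. At amplitude/noise 10 the detector exceeds 0.95 precision and
recall against generator ground truth (measured over 50 sweeps). The
acquisition-software detector used for the original recordings is not
described anywhere, so this detector is the package's own, with all
parameters exposed.

## Statistics: conventions and numerical choices

- **GG dfs always reported.** The repeated-measures F is computed from
  the standard within-subject decomposition; the Greenhouse–Geisser ε
  comes from the double-centered covariance of level scores (pooled
  within-group covariance for mixed designs), clipped to
  [1/(k−1), 1], and ε-scaled dfs are reported even when ε = 1 — the
  convention under which SPSS-style outputs such as "F (2.000, 12.00)"
  arise. ε = 1 exactly for k = 2, where F equals the squared paired t.
- **Mixed ANOVA** uses the univariate cell-mean decomposition (group
  tested against subjects-within-groups; within and interaction against
  the subject × treatment residual), with GG applied to the within
  terms. F statistics agree with pingouin to machine precision on
  balanced designs; ε differs from pingouin's (which pools across
  groups without centering per group) by design.
- **Two-way between-subjects ANOVA** is Type III via OLS with sum
  contrasts (statsmodels); empty cells raise.
- **Unpaired t** uses pooled variance (df = n₁ + n₂ − 2, matching the
  df bookkeeping of two-group cell comparisons); Welch is deliberately
  not used. Zero-variance-zero-difference inputs define t = 0, p = 1.
- **Kruskal–Wallis** is tie-corrected; the post-hoc is Dunn's rank test
  with Sidak adjustment (chosen for consistency with the parametric
  post-hoc; the original analysis does not name one).
- **Sidak**: p_adj = 1 − (1 − p)^m, m = all pairwise contrasts of the
  factor unless stated otherwise.
- **Assumption checks**: one-sample KS against a normal with
  sample-estimated mean/sd on pooled centered residuals, and Levene with
  median centering. With estimated parameters the KS test is
  conservative (rejection rate below nominal), which the tests assert as
  such rather than pretending uniformity. Constant samples are flagged
  degenerate.
- **Calibration null generators.** The GG-corrected tests are
  calibrated under a *non-spherical* within-subject covariance (unequal
  variances plus correlation) — the regime the correction exists for —
  where their empirical size is 0.05 ± 0.01 at 2000 replicates. Under
  perfect sphericity GG is mildly conservative (≈0.04 at n = 7, k = 3),
  which is expected behavior, not an error.

## Pipeline

Per-figure analyses are data-driven recipes (`recipes/default.yaml`):
each names a table, a test and its factors, so new analyses are
additions, not code edits. Synthetic runs are fully seeded and
deterministic (byte-identical reports for identical config + seed);
source-data mode touches no random stream. Stage boundaries log counts
(bouts excluded, windows dropped) so filtering is auditable. Excluded
bouts are carried through with reasons rather than silently dropped.

## Problem sizes

Monte-Carlo checks use sizes chosen to give tight enough binomial error
while staying desk-scale: 2000 replicates for test calibration
(binomial SE ≈ 0.005 at 0.05), 100 replicate experiments for recovery
and power at the study's n = 7, 50 sweeps for detector operating
characteristics, and 6–8 cells at 2 kHz sampling for the 40-min
bath-application recovery (detection at 2 kHz remains accurate for
5-ms-decay events and keeps the 40-min traces small).

## Known limitations

- No isosbestic/reference-channel motion correction and no bleaching
  correction; sessions with strong drift bias ΔF/F (testable via the
  generator's drift term).
- The evoked E/I uses peak amplitudes, not charge.
- Access-resistance screening is honored as per-cell metadata, not
  recomputed from test pulses.
- The mixed-ANOVA decomposition assumes (near-)balanced groups; heavily
  unbalanced designs should use a mixed-effects model instead.
- Kinetics estimates (10–90% rise, 1/e decay) are sample-resolution
  measurements, not fitted time constants.
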