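# pairbond

Analysis pipeline for pair-bonding neurophysiology experiments in
monogamous voles: event-aligned fiber-photometry ΔF/F quantification,
partner-preference behavioral scoring, whole-cell patch-clamp summaries
(spontaneous/evoked postsynaptic currents, excitability), and the
statistical comparisons that tie them together — exercised end-to-end on
a synthetic-data generator with known ground truth.

## The problem

Pair-bond formation changes how the nucleus accumbens (NAc) shell
responds to a partner: dopamine release and D1 medium-spiny-neuron (MSN)
activity increase, D2 MSN activity decreases, and synaptic transmission
onto both populations is remodeled. Quantifying this requires a chain of
small, exacting steps — baselining fluorescence, aligning it to scored
behavior bouts, excluding bouts that ride on a previous response,
detecting spontaneous synaptic events, and applying repeated-measures
statistics with the right sphericity conventions. This package
implements that chain as a tested library so every step is auditable and
reusable on either synthetic or real long-format data.

## Core quantities

- **ΔF/F** = (F − F₀)/F₀, with F₀ the mean fluorescence over the 10 s
  before stimulus exposure; one F₀ per exposure epoch. A bout's response
  is the mean ΔF/F over the fixed 4-s window after bout onset; bouts
  starting within 4 s of the previous retained bout's offset are
  excluded.
- **Social preference ratio** = (P − S)/(P + S) on partner-side vs
  stranger-side times in the 3-h three-chamber test.
- **sPSC statistics**: frequency = events/duration, amplitude = mean
  |peak|, from matched-filter detection with a biexponential template.
- **E/I ratio** = mean |evoked EPSC| / mean |evoked IPSC| per cell
  (20 trials per holding potential, baseline-subtracted), normalized to
  the control-group mean.
- **F–I curve / rheobase** from 1000-ms current steps (0–250 pA).
- **Statistics**: paired/unpaired t (pooled variance), one-way RM ANOVA
  and mixed ANOVA with the Greenhouse–Geisser correction (ε-scaled dfs
  always reported), two-way Type III ANOVA, Sidak post-hocs,
  Kruskal–Wallis with Dunn post-hoc, KS/Levene assumption checks.

## Worked example

```bash
python analysis/02_photometry_quantification.py
```

simulates two cohorts of 7 animals (cohabitation day 3 and day 7; one
30-min exposure each to partner, stranger and object) and quantifies
bout-locked responses:

```
day3: mean dF/F over the 4-s response window (%, n=7 animals)
object     -0.064
partner     0.824
stranger    0.806
  one-way RM ANOVA (GG): F (1.883, 11.30) = 355.6, p = 7.628e-11
  Sidak partner vs stranger: p_adj = 0.948

day7: mean dF/F over the 4-s response window (%, n=7 animals)
object      0.033
partner     1.695
stranger    0.837
  one-way RM ANOVA (GG): F (1.469, 8.81) = 859, p = 1.623e-10
  Sidak partner vs stranger: p_adj = 7.902e-06
```

On day 3 partner and stranger evoke indistinguishable responses; on
day 7 the partner response is roughly double the stranger response and
the Sidak-adjusted contrast is significant — the generator's configured
effect structure, recovered by the full pipeline. The other drivers
(`analysis/01…05`) cover data serialization, patch-clamp summaries,
chemogenetic preference behavior, and the end-to-end report bundle; the
same computations are available from the `pairbond` CLI
(`pairbond simulate|analyze|stats|report`).

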