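# vocometric

Noise-vocoded speech synthesis and psychometric analysis of degraded-speech
intelligibility.

Understanding speech that has been acoustically degraded — a bad phone line, a
heavy cold, background babble — is a demanding computation for the auditory
brain, and it is disproportionately impaired in Alzheimer's disease and in the
primary progressive aphasias (PPA). A standard laboratory model of such
degradation is **noise-vocoding**: the speech signal is split into `N`
contiguous frequency bands ("channels"), each band's temporal fine structure
is replaced with white noise modulated by that band's amplitude envelope, and
the bands are summed. Fewer channels carry less spectral detail, so
intelligibility falls; the number of channels a listener needs to identify 50%
of spoken digits correctly is a graded, quantifiable **intelligibility
threshold** with diagnostic value.

`vocometric` implements the full analysis chain for digit-identification
experiments of this kind, and a synthetic-data module that simulates the whole
study (stimuli, listeners, multi-group cohorts), so every stage can be
exercised and validated end to end without access to patient data.

## The model

A listener's probability of reporting a digit correctly at a level of
`2^x` vocoding channels is a Weibull psychometric function on the
log2-channel axis `x`, scaled between a guess rate γ and a lapse rate λ:

    ψ(x) = γ + (1 − γ − λ) · [1 − exp(−(x/α)^β)]

Per-level digit counts are binomial, or beta-binomial with overdispersion
η ∈ [0, 1): the latent per-trial success probability has variance
η²·p(1−p), so η = 0 recovers the binomial exactly. Parameters are estimated
by maximum likelihood (coarse grid + bounded multi-start L-BFGS-B), and each
fit reports:

* **threshold** — channels at which ψ reaches an absolute 50% correct
  (`2^x50`),
* **slope** — dψ/dx at that point (per log2-channel),
* **γ, λ, η** — guess, lapse, overdispersion.

Group comparisons use tie-corrected Kruskal–Wallis tests with the
η²_H = (H − k + 1)/(n − k) effect size, Dunn's post hoc z-tests, Spearman
correlations, and an upper-quantile outlier-sensitivity rule. Diagnostic
discrimination of each patient group from controls is quantified by the
threshold's ROC AUC (empirical/Mann–Whitney with a DeLong CI, and a binormal
estimator with a bootstrap CI).

## Worked example

Simulate one healthy-control listener over the standard 100-item design
(4 clear-speech items, then 4 items at every channel count from 24 down
to 1), aggregate digit scores, and fit the psychometric function:

```python
import vocometric as vm

design = vm.build_stimulus_list(seed=0)
params = vm.ListenerParams(m=3.14, s=1.08, gamma=0.04, lam=0.0, eta=0.0)
trials = vm.simulate_listener(params, design, seed=7)
data = vm.aggregate(trials, "P000")

est = vm.WeibullPsychometric().fit(data.channels, data.k, data.n)
print(f"threshold = {est.threshold_:.2f} channels")
print(f"slope     = {est.slope_:.2f} per log2-channel")
print(f"gamma     = {est.gamma_:.3f}   lam = {est.lam_:.3f}   eta = {est.eta_:.3f}")
```

prints

```
threshold = 3.12 channels
slope     = 1.57 per log2-channel
gamma     = 0.051   lam = 0.017   eta = 0.000
```

The fitted threshold (3.12) recovers this listener's generating threshold of
3.14 channels from just 12 digit datapoints per level; the slope is noisier,
as expected at this trial count.

The same chain runs from the shell. `vocometric replicate --seed 42 --out run/`
simulates the default five-group cohort (25 controls, 19 Alzheimer's disease,
8 lvPPA, 10 nfvPPA, 12 svPPA — 74 listeners), fits everyone, and writes the
trial/fit CSVs plus stats and ROC reports, e.g.:

```
Synthetic replication (seed=42, config 8f3bf9f98ab525d0)
Listeners fitted: 74  (converged: 73)

Group means (SD) by psychometric parameter:
  threshold: Controls 3.13 (0.45), AD 4.22 (1.24), lvPPA 5.79 (2.42), nfvPPA 4.18 (2.10), svPPA 3.50 (0.54)
    omnibus H(4) = 13.11, p = 0.0108, eta2_H = 0.132
  ...
```

Controls sit near 3 channels and every patient group shifts upward, with the
omnibus test picking up the group effect in a single simulated cohort.
Individual WAV files can be vocoded directly:
`vocometric vocode --in x.wav --channels 8 --seed 7 --out x_ch8.wav`
(or `--sweep 1:24` for a full manifest).

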