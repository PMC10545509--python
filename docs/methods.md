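# Methods

This note documents the models, parameter choices and numerical decisions
behind `vocometric`, and what the synthetic-data pipeline does and does not
establish about real listeners.

## Noise vocoder

The vocoder divides the analysis range [`f_lo`, `f_hi`] = [100, 6400] Hz into
`n_channels` contiguous bands with edges equally spaced in log-frequency,
`edge_k = f_lo · (f_hi/f_lo)^(k/N)`. Log spacing is the standard choice for
speech vocoders because it approximates cochlear frequency resolution; the
edges, range and filter settings are all configurable rather than fixed,
since published vocoder studies vary in these details.

Per channel the input is band-pass filtered (4th-order Butterworth, applied
forward-backward with `sosfiltfilt` so envelope and carrier stay time-aligned
and the effective magnitude response is |H|²), its envelope extracted by
half-wave rectification plus a zero-phase 4th-order low-pass at
`env_cutoff` = 30 Hz (Hilbert magnitude available behind a flag), and a fresh
white Gaussian noise carrier is multiplied by the envelope and re-filtered
into the band. Double-filtering the modulated carrier bounds spectral
splatter outside the channel. The channel sum is RMS-matched to the input to
1e-6 relative; if the peak then exceeds full scale the signal is rescaled
(never clipped), which sacrifices exact RMS equality only for inputs with
almost no headroom. At the band edges adjacent |H|² responses are power
complementary, so the summed response stays within ±3 dB across the analysis
range for orders ≥ 4.

Clear speech is represented as the unprocessed signal, not as a large-`N`
vocode. All noise flows from the config seed: vocoding is a pure function of
(signal, config).

## Synthetic utterances and design

`synth_utterance` is a stand-in for recorded spoken three-digit numbers: three
harmonic-complex segments, one per digit, whose fundamental, spectral
centroid, AM rate and duration all depend on the digit, separated by short
gaps (~1.4 s total). It reproduces the properties the pipeline actually
exploits — distinct broadband envelopes and spectral trajectories per number,
energy confined to 100–6400 Hz — and nothing else: no phonetics, no
coarticulation, no talker variability. Peak amplitude is normalised to 0.5;
this headroom keeps RMS-matched noise vocoding clip-free despite the higher
crest factor of noise carriers.

The design is fixed: 100 distinct three-digit numbers, 4 presented clear
first and then 4 per channel count in descending order 24 → 1, i.e. 12 digit
datapoints per vocoded level (4 trials × 3 digits). Only the assignment of
numbers to slots is randomised.

## Generative listener model

A simulated listener is parameterised by the quantities the analysis reports:
threshold `m` (channels), slope `s` at threshold (per log2-channel), guess
rate γ, lapse rate λ, overdispersion η. These are converted to the Weibull
(α, β) by inverting the threshold and slope equations in closed form. Digit
successes are Bernoulli draws of a trial-level probability p̃: with η = 0,
p̃ = ψ(x); otherwise p̃ ~ Beta with mean ψ(x) and variance η²·ψ(1−ψ)
(concentration ν = 1/η² − 1). The beta draw is per trial, not per digit,
because the three digits of a trial share one acoustic token — within-trial
correlation is the natural carrier of extra-binomial variance. A consequence
worth noting: at the per-level count granularity (12 digits pooled over 4
independent trials) the variance inflation is only 1 + 2η², so modest η is
hard to detect from count dispersion at this design size; the dispersion
tests therefore operate at trial granularity. Clear trials use p = 1 − λ.

Cohorts draw each listener's parameters from per-group normal distributions
truncated to valid ranges: threshold ≥ 1.1 channels (the log2
re-parameterisation degenerates at exactly 1 channel), slope in [0.1, 4.0]
(near-flat curves are unfittable; steeper than 4/log2-channel is outside the
observable range of this design), γ and λ in [0, 0.25], η fixed at the group
mean. The default five-group cohort (25 controls, 19 Alzheimer's disease, 8
logopenic-, 10 non-fluent- and 12 semantic-variant PPA; 74 listeners) uses
the group means/SDs of the clinical profile this package replicates:
controls at threshold 3.14 ± 0.27 channels, patient groups shifted up to
3.55–5.35 with SDs up to 2.2. All randomness descends from one seed through
hierarchically spawned generators.

## Psychometric fitting

Maximum likelihood over (α, β, γ, λ, η), binomial or beta-binomial per level.
Design choices:

* **MLE rather than Bayesian integration.** Only point estimates of the five
  parameters are consumed downstream; MLE keeps the module dependency-light.
  No priors; bounds α ∈ (0.01, log2 48], β ∈ (0.1, 20], γ, λ ∈ [0, 0.25],
  η ∈ [0, 0.95].
* **Initialisation.** A 15 × 9 grid over (α, β) at small fixed asymptotes and
  η = 0 seeds the top 3 L-BFGS-B starts (ftol 1e-9). The procedure is fully
  deterministic for fixed data and options.
* **Numerics.** ψ is clipped to [1e-9, 1−1e-9] before mass evaluation; below
  η = 1e-8 the exact binomial branch is used, making the η → 0 limit exact
  rather than numerically fragile (the beta-binomial matches the binomial to
  < 1e-4 already at η = 1e-4).
* **Threshold definition.** Absolute 50% correct, not the asymptote
  midpoint: `x50` solves γ + (1−γ−λ)F(x50) = 1/2, inverted in closed form
  (the Weibull quantile function is analytic, so no iterative solve is
  needed). If 1 − λ ≤ 0.5 the threshold is structurally undefined and a
  distinct `UndefinedThresholdError`/flag is raised, never a numeric failure.
* **Slope.** Analytic derivative of ψ at `x50`, on the log2-channel axis;
  values around 0.8–1.1 per log2-channel are typical at these designs.
* **Degenerate data.** All-floor or all-ceiling counts yield a flagged
  boundary fit; optimizer non-convergence is flagged, with best-found
  parameters returned. Clear-speech trials never enter the fit (the channel
  axis is undefined for them); they are summarised as a ceiling check.

At the study design (12 digits per level, 24 levels) the fit recovers a
control-like threshold essentially without bias: the grand mean over
repeated simulated cohorts sits within a few hundredths of a channel of the
generating 3.14 (see `scripts/acceptance.py`), and the median single-listener
recovery error is well under 10%.

## Group statistics

Kruskal–Wallis H (tie-corrected, χ²_{k−1} tail) with the effect size
η²_H = (H − k + 1)/(n − k); this normalisation makes the null expectation 0,
and small negative values are reported as computed. Dunn's post hoc z uses
jointly computed ranks with the tie-corrected pooled variance; p-values are
reported unadjusted by default (a Holm option exists) because the downstream
consumer is a per-pair report, not a family-wise claim. Spearman correlation
is Pearson on average ranks with the t approximation. The outlier rule flags
values strictly above the 97.5th empirical percentile
(linear-interpolation convention) for sensitivity re-analysis.

## ROC analysis

Orientation: higher threshold ⇒ case. The empirical AUC is the Mann–Whitney
pair-winning probability (ties one half) with a DeLong variance CI; the
binormal AUC is Φ((μ_case − μ_control)/√(σ²_case + σ²_control)) from sample
moments with a 2000-replicate bootstrap CI. The empirical estimator is the
default for the synthetic pipeline: the simulated (and the clinical) group
threshold distributions are visibly non-normal — the control SD (0.27) is an
order of magnitude below the patient SDs — so the binormal estimator's
normality assumption is dubious, and both are surfaced rather than hidden.
On large normal samples the two agree to Monte-Carlo error.

## Problem sizes in the standard runs

The acceptance script uses 20 simulated-and-refitted cohorts of 25 control
listeners for threshold recovery (500 full fits) and 500 cohort draws of
25 + 12 listeners for the AUC distribution; the test suite uses the same or
smaller sizes. These sizes put Monte-Carlo error comfortably inside the
tolerances being checked while keeping a full run in tens of seconds.

## Limitations

* The synthetic utterances are not speech; nothing here validates digit
  *recognition*, only the scoring → fitting → statistics chain downstream of
  it. Passing tests show the pipeline recovers the parameters of listeners
  who behave like the generative model, not that human listeners do.
* The generative model draws the five psychometric parameters independently
  per listener; real parameter correlations (e.g. threshold with lapse) are
  not modelled.
* Trial-level overdispersion is a modelling choice; whether within-trial
  digit errors are correlated in humans is unknown.
* Strict positional digit scoring is assumed; transpositions ("578" for
  "587") score 1. The alignment convention for partial responses
  (left-aligned to hundreds) is documented and configurable upstream of
  scoring, not inferred from data.
* The binormal AUC on truncated-normal threshold distributions is an
  approximation by construction; the empirical estimator is authoritative
  here.
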