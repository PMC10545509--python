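"""Synthetic study generator: stimuli, design, listeners and cohorts.

The real experiment presented 100 spoken three-digit numbers — 4 in clear
speech and 4 at every vocoding level from 24 channels down to 1 — and scored
the digits each listener reported.  This module generates all of that
synthetically:

* :func:`synth_utterance` builds a harmonic-complex stand-in for a recorded
  spoken number, deterministic per (digits, seed);
* :func:`build_stimulus_list` lays out the 100-item design in descending
  channel order;
* :func:`simulate_listener` produces trial-level digit responses from a
  Weibull psychometric observer with guess/lapse asymptotes and optional
  beta-distributed trial-level overdispersion;
* :func:`simulate_cohort` draws listeners for the five diagnostic groups
  (healthy controls, typical Alzheimer's disease, and the logopenic,
  non-fluent and semantic variants of primary progressive aphasia) from
  truncated normal distributions over the psychometric parameters, returning
  both the trial data and the ground-truth draws for recovery testing.

All randomness descends from a single seed through hierarchically spawned
generators, so cohorts, listeners and trials are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .audio import AudioSignal
from .psychometric import predict_pcorrect, weibull_from_threshold_slope
from .scoring import CLEAR_LEVEL, TRIAL_COLUMNS, score_trial

__all__ = [
    "ListenerParams",
    "GroupSpec",
    "CohortSpec",
    "default_cohort_spec",
    "synth_utterance",
    "build_stimulus_list",
    "simulate_listener",
    "draw_listener_params",
    "simulate_cohort",
]

# Truncation bounds for parameter draws.  Thresholds below ~1 channel are not
# meaningful (the stimulus axis starts at 1) and the log2 re-parameterisation
# degenerates at exactly 1; near-zero slopes produce unfittable flat curves.
THRESHOLD_FLOOR = 1.1
SLOPE_RANGE = (0.1, 4.0)
RATE_RANGE = (0.0, 0.25)

CHANNEL_LEVELS = tuple(range(1, 25))
TRIALS_PER_LEVEL = 4
N_CLEAR = 4


@dataclass(frozen=True)
class ListenerParams:
    """Generating psychometric parameters for one simulated listener.

    ``m``: true 50% threshold in channels; ``s``: slope at threshold per
    log2-channel; ``gamma``/``lam``: guess and lapse rates; ``eta``:
    overdispersion in [0, 1).
    """

    m: float
    s: float
    gamma: float = 0.0
    lam: float = 0.0
    eta: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 1.0:
            raise ValueError(f"threshold m must be >= 1 channel, got {self.m}")
        if self.s <= 0:
            raise ValueError(f"slope s must be positive, got {self.s}")
        if not (0.0 <= self.gamma <= 0.25 and 0.0 <= self.lam <= 0.25):
            raise ValueError("gamma and lam must lie in [0, 0.25]")
        if self.gamma + self.lam >= 1.0:
            raise ValueError("gamma + lam must be < 1")
        if not 0.0 <= self.eta < 1.0:
            raise ValueError(f"eta must lie in [0, 1), got {self.eta}")


@dataclass(frozen=True)
class GroupSpec:
    """Population distribution of psychometric parameters for one group."""

    label: str
    n: int
    threshold_mean: float
    threshold_sd: float
    slope_mean: float
    slope_sd: float
    lam_mean: float
    lam_sd: float
    gamma_mean: float
    gamma_sd: float
    eta_mean: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r} must have n >= 1")
        for name in ("threshold_sd", "slope_sd", "lam_sd", "gamma_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """An ordered collection of groups with unique labels."""

    groups: tuple[GroupSpec, ...]

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")
        if not self.groups:
            raise ValueError("cohort must contain at least one group")

    def __iter__(self):
        return iter(self.groups)

    def total_n(self) -> int:
        return sum(g.n for g in self.groups)


def default_cohort_spec() -> CohortSpec:
    """Five-group study population: healthy controls and four dementia syndromes.

    Group sizes and per-group psychometric parameter means/SDs (threshold in
    channels, slope per log2-channel, lapse, guess, overdispersion) follow the
    published clinical profile this package replicates synthetically:
    controls cluster tightly near a 3-channel threshold while the patient
    groups shift upward with much wider spread.
    """
    rows = [
        #      label      n  thr_m thr_sd slp_m slp_sd lam_m lam_sd gam_m gam_sd eta
        ("Controls", 25, 3.14, 0.27, 1.08, 0.90, 0.00, 0.01, 0.04, 0.07, 0.00),
        ("AD",       19, 4.33, 1.25, 0.79, 0.27, 0.02, 0.02, 0.00, 0.01, 0.04),
        ("lvPPA",     8, 5.35, 2.13, 0.82, 0.36, 0.03, 0.03, 0.00, 0.00, 0.04),
        ("nfvPPA",   10, 4.68, 2.22, 0.81, 0.27, 0.02, 0.02, 0.00, 0.00, 0.00),
        ("svPPA",    12, 3.55, 0.53, 0.95, 0.46, 0.02, 0.03, 0.00, 0.00, 0.00),
    ]
    return CohortSpec(tuple(GroupSpec(*row) for row in rows))


# ---------------------------------------------------------------------------
# Stand-in audio
# ---------------------------------------------------------------------------

def synth_utterance(digits: str, rate: float = 16000.0, seed: int = 0) -> AudioSignal:
    """Synthesize a spoken-number stand-in for a three-digit string.

    Three harmonic-complex segments (~0.4 s each, one per digit) separated by
    short gaps: each digit sets its segment's fundamental, spectral centroid,
    amplitude-modulation rate and duration, so different numbers have
    distinct amplitude envelopes and spectral trajectories.  Content spans
    roughly 100-6400 Hz; output is deterministic per (digits, rate, seed)
    with peak amplitude 0.5 — the headroom keeps RMS-matched noise vocoding
    clip-free despite the higher crest factor of noise carriers.
    """
    if len(digits) != 3 or not digits.isdigit() or digits[0] == "0":
        raise ValueError(f"digits must be a 3-digit string 100-999, got {digits!r}")
    rng = np.random.default_rng(seed)
    gap = np.zeros(int(0.06 * rate))
    pieces = []
    for ch in digits:
        d = int(ch)
        dur = 0.36 + 0.012 * d
        t = np.arange(int(dur * rate)) / rate
        f0 = 120.0 + 9.0 * d + rng.uniform(-2.0, 2.0)
        centroid = 500.0 + 320.0 * d + rng.uniform(-40.0, 40.0)
        n_harm = int(6400.0 // f0)
        h = np.arange(1, n_harm + 1)
        weights = np.exp(-0.5 * ((h * f0 - centroid) / 900.0) ** 2) + 0.05
        phases = rng.uniform(0, 2 * np.pi, n_harm)
        seg = (weights[:, None] * np.sin(2 * np.pi * np.outer(h * f0, t)
                                         + phases[:, None])).sum(axis=0)
        am = 1.0 + 0.4 * np.sin(2 * np.pi * (3.0 + 0.5 * d) * t)
        ramp = np.minimum(1.0, np.minimum(t, dur - t) / 0.03)
        pieces += [seg * am * ramp, gap]
    out = np.concatenate(pieces[:-1])
    out *= 0.5 / np.max(np.abs(out))
    return AudioSignal(out, rate)


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------

def build_stimulus_list(seed: int = 0) -> pd.DataFrame:
    """The 100-item presentation design: 4 clear then 4 per level, 24 down to 1.

    100 distinct three-digit numbers are sampled without replacement and
    assigned in presentation order; the level structure is fixed by design,
    only the number-to-slot assignment is randomised.  Columns: stimulus_id,
    digits, level ("clear" or channel count), filename.
    """
    rng = np.random.default_rng(seed)
    numbers = rng.choice(np.arange(100, 1000), size=100, replace=False)
    levels: list[object] = [CLEAR_LEVEL] * N_CLEAR
    for ch in sorted(CHANNEL_LEVELS, reverse=True):
        levels += [ch] * TRIALS_PER_LEVEL
    records = []
    for i, (num, level) in enumerate(zip(numbers, levels)):
        records.append({
            "stimulus_id": f"S{i:03d}",
            "digits": str(num),
            "level": level,
            "filename": f"{num}_{level}.wav",
        })
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Listener and cohort simulation
# ---------------------------------------------------------------------------

def _trial_probability(params: ListenerParams, level) -> float:
    if str(level) == CLEAR_LEVEL:
        return 1.0 - params.lam
    alpha, beta = weibull_from_threshold_slope(params.m, params.s,
                                               params.gamma, params.lam)
    return float(predict_pcorrect(np.log2(float(level)), alpha, beta,
                                  params.gamma, params.lam))


def simulate_listener(params: ListenerParams, design: pd.DataFrame,
                      seed: int | np.random.Generator = 0,
                      participant_id: str = "P000",
                      group: str = "sim") -> pd.DataFrame:
    """Simulate one listener's digit responses over the stimulus design.

    At level x the expected digit-success probability is the listener's
    psychometric function p(log2 x); clear trials use the ceiling 1 - lam.
    With eta > 0 each trial draws a latent success probability from a Beta
    distribution with mean p and variance eta^2 * p * (1 - p) — all three
    digits of a trial share one acoustic token, so the overdispersion acts at
    trial level.  Responses are full three-digit strings; wrong slots get a
    uniformly random incorrect digit.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for idx, stim in enumerate(design.itertuples(index=False)):
        p = np.clip(_trial_probability(params, stim.level), 1e-9, 1.0 - 1e-9)
        if params.eta > 0:
            nu = 1.0 / params.eta**2 - 1.0
            p_trial = rng.beta(p * nu, (1.0 - p) * nu)
        else:
            p_trial = p
        target = str(stim.digits)
        response = []
        for slot in range(3):
            if rng.random() < p_trial:
                response.append(target[slot])
            else:
                wrong = rng.integers(0, 9)
                if wrong >= int(target[slot]):
                    wrong += 1
                response.append(str(wrong))
        response = "".join(response)
        rows.append({
            "participant_id": participant_id,
            "group": group,
            "trial_index": idx,
            "level": stim.level,
            "target_digits": target,
            "response_digits": response,
            "digits_correct": score_trial(target, response),
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _truncated_draw(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def draw_listener_params(group: GroupSpec,
                         rng: np.random.Generator) -> ListenerParams:
    """Draw one listener's generating parameters from a group's distributions.

    Normal draws truncated to valid ranges: threshold >= 1.1 channels, slope
    in [0.1, 4], guess/lapse in [0, 0.25]; eta is the group mean.
    """
    return ListenerParams(
        m=_truncated_draw(rng, group.threshold_mean, group.threshold_sd,
                          THRESHOLD_FLOOR, np.inf),
        s=_truncated_draw(rng, group.slope_mean, group.slope_sd, *SLOPE_RANGE),
        gamma=_truncated_draw(rng, group.gamma_mean, group.gamma_sd, *RATE_RANGE),
        lam=_truncated_draw(rng, group.lam_mean, group.lam_sd, *RATE_RANGE),
        eta=float(np.clip(group.eta_mean, 0.0, 0.95)),
    )


def simulate_cohort(spec: CohortSpec, design: pd.DataFrame,
                    seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate every listener in a multi-group cohort.

    Returns ``(trials, truth)``: the concatenated trial table and the
    ground-truth parameter draws (participant_id, group, m, s, gamma, lam,
    eta) used to generate them.
    """
    root = np.random.SeedSequence(seed)
    group_seqs = root.spawn(len(spec.groups))
    trial_frames, truth_rows = [], []
    for group, seq in zip(spec.groups, group_seqs):
        listener_seqs = seq.spawn(group.n)
        for i, lseq in enumerate(listener_seqs):
            rng = np.random.default_rng(lseq)
            params = draw_listener_params(group, rng)
            pid = f"{group.label}-{i:02d}"
            trial_frames.append(
                simulate_listener(params, design, rng, participant_id=pid,
                                  group=group.label)
            )
            truth_rows.append({
                "participant_id": pid, "group": group.label,
                "m": params.m, "s": params.s, "gamma": params.gamma,
                "lam": params.lam, "eta": params.eta,
            })
    trials = pd.concat(trial_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth
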