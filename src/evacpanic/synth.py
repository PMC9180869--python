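"""Synthetic cohorts with the statistical structure the analysis assumes.

The study's raw participant data are not publicly deposited, so this module
generates cohorts that emulate the features the downstream indicators
measure: stimulus-locked pupil-dilation bumps with blink gaps,
fixation/saccade alternation at scenario-specific rates, gaze that mixes
clustered dwelling with wide scanning, HRF-shaped ΔHbO responses buried in
drift and physiological noise, and 9-point questionnaire scores with
per-scenario shifts.

Defaults for every effect size are the cohort-level values the study
reports (pupil amplitude means/SDs, fixation/saccade time ratios, per
channel activation-coefficient moments, emotion-shift moments); the
generator treats them as the true per-scenario population parameters.
Everything is driven by a single master seed: each participant receives an
independent child stream, so identical configurations reproduce cohorts
bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .emotion import ALL_TERMS
from .eye import DEFAULT_PLANE, EyeRecording
from .fnirs import FnirsRecording, HrfModel, build_regressor, canonical_hrf
from .timeline import SEQUENCES, SessionTimeline, build_timeline

STIMULI = ("Alarm", "Smoke", "Flame")
ALL_SCENARIOS = ("Roaming",) + STIMULI


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Default effect profiles (cohort-level truths)
# ---------------------------------------------------------------------------

PUPIL_AMPLITUDE_MEAN = {"Alarm": 1.46, "Smoke": 1.31, "Flame": 1.32}
PUPIL_AMPLITUDE_SD = {"Alarm": 0.24, "Smoke": 0.14, "Flame": 0.18}

FIXATION_RATIO = {"Roaming": 0.863, "Alarm": 0.835, "Smoke": 0.887, "Flame": 0.903}
SACCADE_RATIO = {"Roaming": 0.052, "Alarm": 0.063, "Smoke": 0.040, "Flame": 0.027}

# mixing weight of the wide-scanning gaze regime (vs clustered dwelling);
# ordered to reproduce the reported entropy ranking
# Roaming ≈ Alarm > Flame ≈ Smoke
SCANNING_WEIGHT = {"Roaming": 0.70, "Alarm": 0.65, "Smoke": 0.25, "Flame": 0.30}

BETA_MEAN = {
    "Alarm": (5.71, 5.32, 5.01, 4.46, 5.18, 5.40, 5.52, 5.04),
    "Smoke": (3.13, 3.14, 2.88, 2.91, 3.20, 2.36, 2.79, 2.09),
    "Flame": (4.85, 4.14, 4.32, 3.77, 4.44, 4.31, 3.68, 3.42),
}
BETA_SD = {
    "Alarm": (2.69, 2.56, 1.55, 1.68, 2.92, 2.03, 1.94, 1.91),
    "Smoke": (1.89, 2.10, 1.87, 2.01, 1.71, 1.78, 1.59, 1.37),
    "Flame": (2.51, 1.83, 2.74, 1.74, 2.19, 1.81, 2.00, 1.00),
}

EMOTION_SHIFT_MEAN = {
    "sadness": {"Alarm": 1.47, "Smoke": 1.02, "Flame": 1.24},
    "happiness": {"Alarm": -1.47, "Smoke": -1.20, "Flame": -1.36},
    "fear": {"Alarm": 3.67, "Smoke": 2.14, "Flame": 2.49},
    "anger": {"Alarm": 1.07, "Smoke": 0.67, "Flame": 0.76},
    "surprise": {"Alarm": 2.24, "Smoke": 1.18, "Flame": 1.29},
    "disgust": {"Alarm": 1.78, "Smoke": 1.25, "Flame": 1.40},
    "valence": {"Alarm": -2.05, "Smoke": -1.79, "Flame": -1.91},
    "arousal": {"Alarm": 3.73, "Smoke": 2.35, "Flame": 2.64},
    "dominance": {"Alarm": -1.38, "Smoke": -0.80, "Flame": -0.86},
}
EMOTION_SHIFT_SD = {
    "sadness": {"Alarm": 1.68, "Smoke": 1.27, "Flame": 1.56},
    "happiness": {"Alarm": 1.73, "Smoke": 1.64, "Flame": 1.59},
    "fear": {"Alarm": 1.73, "Smoke": 1.65, "Flame": 1.86},
    "anger": {"Alarm": 1.56, "Smoke": 1.29, "Flame": 1.37},
    "surprise": {"Alarm": 2.28, "Smoke": 1.93, "Flame": 2.06},
    "disgust": {"Alarm": 2.02, "Smoke": 1.69, "Flame": 1.95},
    "valence": {"Alarm": 1.34, "Smoke": 1.20, "Flame": 1.38},
    "arousal": {"Alarm": 2.00, "Smoke": 1.79, "Flame": 1.96},
    "dominance": {"Alarm": 1.78, "Smoke": 1.77, "Flame": 1.69},
}
# roaming-baseline score centres: calm exploration — low negative emotions,
# mildly positive valence/happiness, low arousal, high dominance
EMOTION_BASELINE_MEAN = {
    "sadness": 2.0, "happiness": 6.0, "fear": 2.0, "anger": 1.5,
    "surprise": 2.0, "disgust": 1.5, "valence": 6.0, "arousal": 3.0,
    "dominance": 6.0,
}
EMOTION_BASELINE_SD = 1.0

SEQUENCE_COUNTS = {  # counterbalancing split used in the study design (n = 56)
    "Alarm-Smoke-Flame": 26,
    "Smoke-Flame-Alarm": 15,
    "Flame-Alarm-Smoke": 15,
}


# ---------------------------------------------------------------------------
# Config dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EyeProfile:
    """Per-scenario generative parameters for the 60 Hz eye stream.

    ``amplitude`` is the true peak pupil magnification per stimulus
    scenario; the bump rises smoothly after onset (raised cosine), holds a
    plateau at exactly the configured amplitude, and decays back to
    baseline before the round ends.  Fixation/saccade alternation is a
    two-state renewal process whose dwell times are set from the target
    time ratios; gaze mixes clustered dwell points with uniform scanning at
    the scenario's ``scanning_weight``.
    """

    amplitude: dict = field(default_factory=lambda: dict(PUPIL_AMPLITUDE_MEAN))
    fixation_ratio: dict = field(default_factory=lambda: dict(FIXATION_RATIO))
    saccade_ratio: dict = field(default_factory=lambda: dict(SACCADE_RATIO))
    scanning_weight: dict = field(default_factory=lambda: dict(SCANNING_WEIGHT))
    baseline_area: float = 20.0        # device units
    pupil_noise_sd: float = 0.015      # white noise, fraction of baseline area
    bump_start: float = 0.5            # s after onset (clears the 10-sample baseline)
    bump_rise: float = 3.0             # s, raised-cosine rise
    bump_plateau_end: float = 10.0     # s after onset
    bump_end: float = 18.0             # s after onset, decayed to baseline
    blink_rate: float = 10.0           # blinks per minute
    blink_shape: float = 4.0           # gamma-distributed blink durations
    blink_scale: float = 0.0625        # mean 0.25 s
    saccade_dwell: float = 0.05        # s, mean saccade duration
    n_clusters: int = 4
    cluster_sd: float = 15.0           # px, spread of a dwell cluster
    gaze_jitter: float = 2.0           # px, within-fixation tremor
    plane: tuple = DEFAULT_PLANE

    def noiseless(self) -> "EyeProfile":
        """Copy with blinks, pupil noise and gaze scatter switched off."""
        return dataclasses.replace(
            self, pupil_noise_sd=0.0, blink_rate=0.0,
            cluster_sd=0.0, gaze_jitter=0.0,
        )


@dataclass(frozen=True)
class FnirsNoiseSpec:
    """Additive disturbances on the ΔHbO channels.

    Slow-wave drift (a sub-0.01 Hz sinusoid plus a linear trend),
    physiological sinusoids (respiratory ≈ 0.3 Hz, cardiac ≈ 1 Hz — both
    inside the 5 Hz Nyquist band of the 10 Hz device) with random phases
    per channel, and white measurement noise.  Amplitudes share the β
    units (ΔHbO concentration change).
    """

    drift_amplitude: float = 2.0
    drift_freq: float = 0.005
    trend_amplitude: float = 1.0       # linear ramp over the session
    physio: tuple = ((0.3, 0.5), (1.0, 0.3))
    white_sd: float = 0.4

    def __post_init__(self) -> None:
        amps = [self.drift_amplitude, self.trend_amplitude, self.white_sd] + [
            a for _, a in self.physio
        ]
        if any(a < 0 for a in amps):
            raise SynthError("noise amplitudes must be non-negative")

    @classmethod
    def silent(cls) -> "FnirsNoiseSpec":
        return cls(drift_amplitude=0.0, trend_amplitude=0.0, physio=(),
                   white_sd=0.0)


@dataclass(frozen=True)
class EmotionProfile:
    """Baseline score centres and per-scenario shift moments per term."""

    baseline_mean: dict = field(default_factory=lambda: dict(EMOTION_BASELINE_MEAN))
    baseline_sd: float = EMOTION_BASELINE_SD
    shift_mean: dict = field(
        default_factory=lambda: {t: dict(v) for t, v in EMOTION_SHIFT_MEAN.items()}
    )
    shift_sd: dict = field(
        default_factory=lambda: {t: dict(v) for t, v in EMOTION_SHIFT_SD.items()}
    )


@dataclass(frozen=True)
class CohortConfig:
    """Full generative description of a synthetic cohort."""

    n_participants: int = 56
    seed: int = 0
    eye: EyeProfile = field(default_factory=EyeProfile)
    fnirs_noise: FnirsNoiseSpec = field(default_factory=FnirsNoiseSpec)
    emotions: EmotionProfile = field(default_factory=EmotionProfile)
    beta_mean: dict = field(default_factory=lambda: {k: tuple(v) for k, v in BETA_MEAN.items()})
    beta_sd: dict = field(default_factory=lambda: {k: tuple(v) for k, v in BETA_SD.items()})
    amplitude_sd: dict = field(default_factory=lambda: dict(PUPIL_AMPLITUDE_SD))
    sequence_counts: dict = field(default_factory=lambda: dict(SEQUENCE_COUNTS))

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise SynthError("n_participants must be ≥ 2")
        if any(sd < 0 for sd in self.amplitude_sd.values()):
            raise SynthError("amplitude SDs must be non-negative")


def participant_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent, reproducible child stream for one participant."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(index,))
    )


# ---------------------------------------------------------------------------
# Eye stream
# ---------------------------------------------------------------------------

def _pupil_bump(t_round: np.ndarray, profile: EyeProfile) -> np.ndarray:
    """Unit-height raised-cosine bump: rise, plateau, decay within the round."""
    w = np.zeros_like(t_round)
    t0, rise = profile.bump_start, profile.bump_rise
    t1, t2 = profile.bump_plateau_end, profile.bump_end
    rising = (t_round >= t0) & (t_round < t0 + rise)
    w[rising] = 0.5 * (1 - np.cos(np.pi * (t_round[rising] - t0) / rise))
    w[(t_round >= t0 + rise) & (t_round < t1)] = 1.0
    falling = (t_round >= t1) & (t_round < t2)
    w[falling] = 0.5 * (1 + np.cos(np.pi * (t_round[falling] - t1) / (t2 - t1)))
    return w


def _segments(timeline: SessionTimeline) -> list[tuple[int, int, str]]:
    """(start, stop, scenario) sample segments at the eye rate; buffers and
    roaming use the Roaming behavioural profile."""
    rate = timeline.eye_rate
    n = timeline.n_samples(rate)
    edges: list[tuple[int, int, str]] = []
    cursor = 0
    for i, label in enumerate(timeline.stimulus_labels):
        a = int(round(timeline.stimulus_onsets[i] * rate))
        b = a + int(round(timeline.round_duration * rate))
        if a > cursor:
            edges.append((cursor, a, "Roaming"))
        edges.append((a, min(b, n), label))
        cursor = min(b, n)
    if cursor < n:
        edges.append((cursor, n, "Roaming"))
    return edges


def simulate_eye(
    timeline: SessionTimeline,
    profile: EyeProfile | None = None,
    seed: int | np.random.Generator = 0,
) -> EyeRecording:
    """Generate one participant's full-session 60 Hz eye stream.

    Both eyes share the behavioural state (fixation/saccade flags, blink
    gaps, gaze target) — the tracker reports them per eye but they are
    near-perfectly coupled — while pupil areas get independent measurement
    noise per eye.
    """
    profile = profile or EyeProfile()
    for scen in STIMULI:
        if scen not in profile.amplitude:
            raise SynthError(f"amplitude profile missing scenario {scen!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = timeline.eye_rate
    n = timeline.n_samples(rate)
    t = np.arange(n) / rate

    # --- pupil magnification truth -------------------------------------
    m_true = np.ones(n)
    for i, label in enumerate(timeline.stimulus_labels):
        a = int(round(timeline.stimulus_onsets[i] * rate))
        b = min(n, a + int(round(timeline.round_duration * rate)))
        m_true[a:b] += (profile.amplitude[label] - 1.0) * _pupil_bump(
            t[a:b] - timeline.stimulus_onsets[i], profile
        )
    base = profile.baseline_area
    noise_sd = profile.pupil_noise_sd * base
    pupil_l = base * m_true + rng.normal(0.0, noise_sd, n) if noise_sd else base * m_true
    pupil_r = base * m_true + rng.normal(0.0, noise_sd, n) if noise_sd else base * m_true.copy()
    pupil_l = np.asarray(pupil_l, dtype=float).copy()
    pupil_r = np.asarray(pupil_r, dtype=float).copy()

    # --- fixation / saccade alternation + gaze -------------------------
    fix = np.zeros(n, dtype=bool)
    sac = np.zeros(n, dtype=bool)
    gaze_x = np.empty(n)
    gaze_y = np.empty(n)
    plane = profile.plane
    for a, b, scen in _segments(timeline):
        r_f, r_s = profile.fixation_ratio[scen], profile.saccade_ratio[scen]
        # dwell means chosen so the expected non-blink time split matches the
        # target ratio pair
        sac_dwell = profile.saccade_dwell
        fix_dwell = sac_dwell * (r_f / r_s) if r_s > 0 else np.inf
        centers = np.column_stack(
            [
                rng.uniform(0.15 * plane[0], 0.85 * plane[0], profile.n_clusters),
                rng.uniform(0.15 * plane[1], 0.85 * plane[1], profile.n_clusters),
            ]
        )
        w = profile.scanning_weight[scen]
        pos = a
        state_fix = True
        while pos < b:
            if state_fix:
                dur = rng.exponential(fix_dwell) if np.isfinite(fix_dwell) else b - pos
                if w > 0 and rng.random() < w:
                    target = np.array(
                        [rng.uniform(0, plane[0]), rng.uniform(0, plane[1])]
                    )
                else:
                    c = centers[rng.integers(profile.n_clusters)]
                    target = c + rng.normal(0.0, profile.cluster_sd, 2)
                target = np.clip(target, 0, [plane[0] - 1e-6, plane[1] - 1e-6])
            else:
                dur = rng.exponential(sac_dwell)
            k = max(1, int(round(dur * rate)))
            stop = min(b, pos + k)
            (fix if state_fix else sac)[pos:stop] = True
            gaze_x[pos:stop] = target[0]
            gaze_y[pos:stop] = target[1]
            pos = stop
            state_fix = not state_fix
    if profile.gaze_jitter > 0:
        gaze_x += rng.normal(0.0, profile.gaze_jitter, n)
        gaze_y += rng.normal(0.0, profile.gaze_jitter, n)
        np.clip(gaze_x, 0, plane[0] - 1e-6, out=gaze_x)
        np.clip(gaze_y, 0, plane[1] - 1e-6, out=gaze_y)

    # --- blinks: Poisson arrivals, gamma durations ---------------------
    if profile.blink_rate > 0:
        expected = profile.blink_rate * timeline.session_duration / 60.0
        n_blinks = rng.poisson(expected)
        starts = np.sort(rng.uniform(0.0, timeline.session_duration, n_blinks))
        durs = rng.gamma(profile.blink_shape, profile.blink_scale, n_blinks)
        blink = np.zeros(n, dtype=bool)
        for s, d in zip(starts, durs):
            i0 = int(round(s * rate))
            i1 = max(i0 + 1, int(round((s + d) * rate)))
            blink[i0:min(i1, n)] = True
        pupil_l[blink] = np.nan
        pupil_r[blink] = np.nan
        gaze_x[blink] = np.nan
        gaze_y[blink] = np.nan
        fix[blink] = False
        sac[blink] = False

    return EyeRecording(
        pupil_left=pupil_l, pupil_right=pupil_r,
        fixation_left=fix, fixation_right=fix.copy(),
        saccade_left=sac, saccade_right=sac.copy(),
        gaze_x=gaze_x, gaze_y=gaze_y, rate=rate,
    )


# ---------------------------------------------------------------------------
# fNIRS stream
# ---------------------------------------------------------------------------

def simulate_fnirs(
    timeline: SessionTimeline,
    true_beta: np.ndarray,
    noise: FnirsNoiseSpec | None = None,
    seed: int | np.random.Generator = 0,
    hrf_model: HrfModel | None = None,
    n_channels: int | None = None,
) -> FnirsRecording:
    """Generate a 10 Hz multi-channel ΔHbO recording.

    ΔHbO_j(t) = Σ_i β_ij (δ ⊗ HRF)_i(t) + drift + physiological sinusoids
    + white noise, with the unit-peak canonical HRF and the presentation
    order taken from the timeline (``true_beta`` rows follow presentation
    order).
    """
    noise = noise if noise is not None else FnirsNoiseSpec()
    hrf_model = hrf_model or HrfModel()
    beta = np.atleast_2d(np.asarray(true_beta, dtype=float))
    if beta.shape[0] != 3:
        raise SynthError(f"true_beta must have 3 stimulus rows, got {beta.shape}")
    if not np.all(np.isfinite(beta)):
        raise SynthError("true_beta must be finite")
    n_channels = beta.shape[1] if n_channels is None else n_channels
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rate = timeline.fnirs_rate
    n = timeline.n_samples(rate)
    t = np.arange(n) / rate
    h = canonical_hrf(hrf_model, rate)
    f = np.stack([build_regressor(timeline, i, h, n, rate) for i in (1, 2, 3)])

    hbo = f.T @ beta  # (n, channels): clean stimulus-locked signal
    for j in range(n_channels):
        if noise.drift_amplitude > 0:
            hbo[:, j] += noise.drift_amplitude * np.sin(
                2 * np.pi * noise.drift_freq * t + rng.uniform(0, 2 * np.pi)
            )
        if noise.trend_amplitude > 0:
            hbo[:, j] += noise.trend_amplitude * (
                2 * t / timeline.session_duration - 1.0
            ) * rng.uniform(-1, 1)
        for freq, amp in noise.physio:
            if amp > 0:
                hbo[:, j] += amp * np.sin(
                    2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)
                )
        if noise.white_sd > 0:
            hbo[:, j] += rng.normal(0.0, noise.white_sd, n)
    return FnirsRecording(hbo=hbo, rate=rate)


# ---------------------------------------------------------------------------
# Questionnaires
# ---------------------------------------------------------------------------

def simulate_emotions(
    profile: EmotionProfile | None = None,
    n: int = 56,
    seed: int | np.random.Generator = 0,
    participant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Generate integer 9-point questionnaire scores for a cohort.

    The roaming baseline is sampled first; scenario scores are the baseline
    plus a normal shift, rounded and clamped into 1..9 — so the *realized*
    shift of a participant near the scale boundary can be smaller than the
    nominal one, exactly as the bounded scale forces on real respondents.

    Returns a long-form table (participant, term, scenario, score).
    """
    profile = profile or EmotionProfile()
    if n < 1:
        raise SynthError("n must be ≥ 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = participant_ids or [f"P{i + 1:03d}" for i in range(n)]
    rows = []
    for pid in ids:
        for term in ALL_TERMS:
            base = int(np.clip(np.round(
                rng.normal(profile.baseline_mean[term], profile.baseline_sd)
            ), 1, 9))
            rows.append({"participant": pid, "term": term,
                         "scenario": "Roaming", "score": base})
            for scen in STIMULI:
                shift = rng.normal(
                    profile.shift_mean[term][scen], profile.shift_sd[term][scen]
                )
                score = int(np.clip(np.round(base + shift), 1, 9))
                rows.append({"participant": pid, "term": term,
                             "scenario": scen, "score": score})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Whole cohort on disk
# ---------------------------------------------------------------------------

def assign_sequences(n: int, counts: dict | None = None) -> list[str]:
    """Deterministic counterbalancing assignment.

    The configured counts (26/15/15 of the three orderings for the default
    cohort size) are rescaled to ``n`` by largest remainder, and assigned
    in participant order.
    """
    counts = counts or dict(SEQUENCE_COUNTS)
    labels = list(counts)
    total = sum(counts.values())
    quotas = {k: n * v / total for k, v in counts.items()}
    alloc = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(alloc.values())
    for k in sorted(labels, key=lambda k: quotas[k] - alloc[k], reverse=True)[:short]:
        alloc[k] += 1
    out = []
    for k in labels:
        out += [k] * alloc[k]
    return out[:n]


def _draw_participant_truth(
    config: CohortConfig, rng: np.random.Generator, sequence: str
) -> dict:
    """Sample one participant's true effect sizes around the cohort moments."""
    amp = {
        s: float(max(1.02, rng.normal(config.eye.amplitude[s],
                                      config.amplitude_sd[s])))
        for s in STIMULI
    }
    order = SEQUENCES[sequence]
    beta = np.array(
        [
            rng.normal(config.beta_mean[scen], config.beta_sd[scen])
            for scen in order
        ]
    )
    return {"amplitude": amp, "beta": beta, "order": order}


def simulate_cohort(config: CohortConfig, out_dir: str | Path) -> dict:
    """Generate and write a full cohort: recordings, questionnaires, manifest.

    Layout::

        out_dir/
          manifest.json
          emotions.csv                      # long-form questionnaire scores
          P001/eye.csv  P001/fnirs.csv  ...

    The manifest records the seed, each participant's sequence label and
    per-participant generative truths (synthetic ground truth for
    parameter-recovery checks).  Identical config + seed reproduce every
    byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sequences = assign_sequences(config.n_participants, config.sequence_counts)
    participants = []
    emotion_frames = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        rng = participant_rng(config.seed, i)
        seq = sequences[i]
        timeline = build_timeline(seq)
        truth = _draw_participant_truth(config, rng, seq)
        profile = dataclasses.replace(config.eye, amplitude=truth["amplitude"])
        eye_rec = simulate_eye(timeline, profile, rng)
        fnirs_rec = simulate_fnirs(timeline, truth["beta"], config.fnirs_noise, rng)
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        eye_rec.to_frame().to_csv(pdir / "eye.csv", index=False, float_format="%.6f")
        fnirs_rec.to_frame().to_csv(
            pdir / "fnirs.csv", index=False, float_format="%.8f"
        )
        emotion_frames.append(
            simulate_emotions(config.emotions, 1, rng, participant_ids=[pid])
        )
        participants.append(
            {
                "id": pid,
                "sequence": seq,
                "eye": f"{pid}/eye.csv",
                "fnirs": f"{pid}/fnirs.csv",
                "truth": {
                    "amplitude": truth["amplitude"],
                    "beta": truth["beta"].round(10).tolist(),
                    "scenario_order": list(truth["order"]),
                },
            }
        )
    pd.concat(emotion_frames, ignore_index=True).to_csv(
        out / "emotions.csv", index=False
    )
    manifest = {
        "n_participants": config.n_participants,
        "seed": config.seed,
        "sequence_counts": {
            s: sequences.count(s) for s in SEQUENCE_COUNTS
        },
        "emotions": "emotions.csv",
        "participants": participants,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest
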