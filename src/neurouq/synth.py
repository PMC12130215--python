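"""Synthetic go/no-go vibration-discrimination sessions with calcium populations.

Emulates the data the decoder and uncertainty analyses assume: an 8-day
discrimination task (go 600 Hz, no-go 200 Hz, probes 240-560 Hz in 40-Hz
steps), a behaving agent with a probit psychometric function, forepaw
trajectories with occasional premovement excursions, and per-session calcium
populations of variable size containing planted go-tuned and lick-tuned
neurons on a GCaMP6f-like difference-of-exponentials kernel.

Trials are 4 s at 30 frames/s (120 frames): pre-stimulus 1 s, stimulus 0.25 s,
delay 0.25 s, response window 1.5 s, post 1 s.  Stimulus onset is frame 31
(1-based); frame indices stored in trial tables are 0-based array indices.

The "ambiguity knob": per-trial multiplicative response gain has dispersion
``gain_variability``, inflated for frequencies configured as ambiguous
(default 240-320 Hz), and the gain is additionally coupled to the trial's lick
decision (``choice_coupling``), so trials where the agent's choice contradicts
the stimulus carry weaker/atypical population signals.  This is what makes
decoding harder, and model uncertainty higher, near the psychometric
threshold and on incorrect trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "FRAME_RATE",
    "N_FRAMES",
    "ONSET_INDEX",
    "PAW_FPS",
    "TaskConfig",
    "AgentParams",
    "PopulationSpec",
    "PopulationRecording",
    "generate_schedule",
    "simulate_behavior",
    "synthesize_population",
    "simulate_paw",
    "simulate_session",
    "simulate_study",
]

FRAME_RATE = 30
N_FRAMES = 120
#: 0-based array index of stimulus onset (frame 31 in 1-based counting:
#: the first frame after the 1-s / 30-frame pre-stimulus baseline).
ONSET_INDEX = 30
PAW_FPS = 160
#: "60 pixels (approximately 3 mm)" implies 1 px = 0.05 mm.
MM_PER_PX = 0.05

_IMAGING_MIX = {"go": 0.36, "no-go": 0.36, "probe": 0.25, "RO": 0.01, "UR": 0.02}
_ADDITIONAL_MIX = {"go": 0.48, "no-go": 0.48, "probe": 0.04}


@dataclass
class TaskConfig:
    """Trial schedule parameters for one session."""

    session_kind: str = "imaging"
    n_trials: int = 200
    phase_durations: tuple = (1.0, 0.25, 0.25, 1.5, 1.0)  # pre, stim, delay, response, post
    iti_range: tuple = (0.5, 2.5)
    frame_rate: int = FRAME_RATE
    stimulus_mix: dict | None = None
    probe_frequencies: tuple = tuple(range(240, 561, 40))
    probe_weights: tuple | None = None  # uniform over the probe set by default
    go_freq: float = 600.0
    nogo_freq: float = 200.0

    def __post_init__(self):
        if self.session_kind not in ("imaging", "additional"):
            raise ValueError(f"unknown session_kind {self.session_kind!r}")
        if self.stimulus_mix is None:
            self.stimulus_mix = dict(
                _IMAGING_MIX if self.session_kind == "imaging" else _ADDITIONAL_MIX
            )
        total = sum(self.stimulus_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stimulus_mix proportions sum to {total}, expected 1")
        if abs(sum(self.phase_durations) - 4.0) > 1e-9:
            raise ValueError("phase durations must sum to 4.0 s (120 frames at 30 fps)")
        for f in self.probe_frequencies:
            if not (self.nogo_freq < f < self.go_freq):
                raise ValueError("probe frequencies must lie strictly between no-go and go")

    @property
    def n_frames(self) -> int:
        return int(round(sum(self.phase_durations) * self.frame_rate))


@dataclass
class AgentParams:
    """Generative psychometric agent: lapse-adjusted probit of frequency.

    lick probability = lapse + (1 - 2*lapse) * Phi(slope * (f - threshold)),
    which equals 0.5 exactly at the threshold.  Response times are Gaussian,
    floored at ``rt_floor`` (0.273 s, the trained animals' minimum response
    time, which also guarantees lick transients fall outside the decoder's
    9-frame stimulus window).
    """

    psychometric_threshold: float = 300.0
    #: expert slope keeps the whole 240-320 Hz probe band inside the
    #: behaviorally ambiguous range (lick probabilities ~0.2-0.6)
    psychometric_slope: float = 0.014  # 1/Hz
    lapse_rate: float = 0.005
    response_time_mean: float = 0.35
    response_time_sd: float = 0.05
    rt_floor: float = 0.273
    learning_stage: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.lapse_rate <= 0.5):
            raise ValueError("lapse_rate must lie in [0, 0.5]")
        if self.psychometric_slope <= 0:
            raise ValueError("psychometric slope must be > 0")

    def lick_probability(self, freq) -> np.ndarray:
        z = self.psychometric_slope * (np.asarray(freq, dtype=float) - self.psychometric_threshold)
        return self.lapse_rate + (1.0 - 2.0 * self.lapse_rate) * norm.cdf(z)

    @classmethod
    def naive(cls) -> "AgentParams":
        return cls(
            psychometric_slope=0.002,
            lapse_rate=0.25,
            response_time_mean=0.8,
            response_time_sd=0.15,
            learning_stage=0.0,
        )

    @classmethod
    def expert(cls) -> "AgentParams":
        return cls(learning_stage=1.0)

    @classmethod
    def for_stage(cls, stage: float) -> "AgentParams":
        """Interpolate naive (0) -> expert (1): slope geometric, the rest linear."""
        s = float(np.clip(stage, 0.0, 1.0))
        na, ex = cls.naive(), cls.expert()
        return cls(
            psychometric_threshold=300.0,
            psychometric_slope=na.psychometric_slope
            * (ex.psychometric_slope / na.psychometric_slope) ** s,
            lapse_rate=na.lapse_rate + s * (ex.lapse_rate - na.lapse_rate),
            response_time_mean=na.response_time_mean
            + s * (ex.response_time_mean - na.response_time_mean),
            response_time_sd=na.response_time_sd + s * (ex.response_time_sd - na.response_time_sd),
            learning_stage=s,
        )


@dataclass
class PopulationSpec:
    """Planted structure of one synthetic calcium population.

    Amplitudes are in units of the additive noise standard deviation, so
    ``response_amplitude / noise_sd`` is the single-trial SNR of a planted
    transient.  ``frac_go_neurons`` / ``frac_lick_neurons`` default to the
    expert-stage proportions (12% / 15%); learning-stage simulations
    interpolate them upward from ~4% / ~1%.
    """

    n_neurons: int = 150
    frac_go_neurons: float = 0.12
    frac_lick_neurons: float = 0.15
    kernel_rise: float = 0.05  # s; GCaMP6f-like
    kernel_decay: float = 0.4  # s
    response_amplitude: float = 3.0
    noise_sd: float = 1.0
    gain_variability: float = 0.25
    ambiguous_frequencies: tuple = (240.0, 280.0, 320.0)
    ambiguity_gain_factor: float = 4.0
    choice_coupling: float = 1.2
    #: go-neuron tuning midpoint sits at the agents' psychometric threshold, so
    #: population amplitude is most ambiguous exactly where behavior is
    tuning_center: float = 300.0
    tuning_width: float = 80.0
    lick_amplitude: float = 3.0
    amplitude_cv: float = 0.2

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        for fr in (self.frac_go_neurons, self.frac_lick_neurons):
            if not (0.0 <= fr <= 1.0):
                raise ValueError("neuron fractions must lie in [0, 1]")
        if self.frac_go_neurons + self.frac_lick_neurons > 1.0 + 1e-9:
            raise ValueError("neuron fractions must sum to <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kernel_rise <= 0 or self.kernel_decay <= 0:
            raise ValueError("kernel time constants must be > 0")


@dataclass
class PopulationRecording:
    """Trial-aligned traces for one session: (n_neurons, 120 frames, n_trials)."""

    traces: np.ndarray
    trial_table: pd.DataFrame
    neuron_ids: list
    frame_rate: int = FRAME_RATE
    session_id: str = "s0"
    mouse_id: str = "m0"
    day: int = 1
    ground_truth: dict = field(default_factory=dict)
    paw: np.ndarray | None = None

    def __post_init__(self):
        n, f, t = self.traces.shape
        if n < 1:
            raise ValueError("recording must contain at least one neuron")
        if f != N_FRAMES:
            raise ValueError(f"expected {N_FRAMES} frames per trial, got {f}")
        if t != len(self.trial_table):
            raise ValueError("trials axis does not match trial table length")
        if len(self.neuron_ids) != n:
            raise ValueError("neuron_ids length does not match traces")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_trials(self) -> int:
        return self.traces.shape[2]


# ---------------------------------------------------------------------------
# schedule
# ---------------------------------------------------------------------------

def generate_schedule(config: TaskConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Stratified trial schedule: exact per-type counts, shuffled; no outcomes yet."""
    if config.n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    counts = {}
    for ttype, p in config.stimulus_mix.items():
        c = p * config.n_trials
        if abs(c - round(c)) > 1e-9:
            raise ValueError(
                f"{ttype} proportion {p} times {config.n_trials} trials is not an "
                f"integer count; choose n_trials compatible with the stimulus mix"
            )
        counts[ttype] = int(round(c))
    types = np.array([t for t, c in counts.items() for _ in range(c)], dtype=object)
    types = types[rng.permutation(len(types))]

    freq = np.full(len(types), np.nan)
    freq[types == "go"] = config.go_freq
    freq[types == "no-go"] = config.nogo_freq
    freq[types == "RO"] = config.go_freq  # reward omission presents a go stimulus
    probe_sel = types == "probe"
    if probe_sel.any():
        w = None
        if config.probe_weights is not None:
            w = np.asarray(config.probe_weights, dtype=float)
            w = w / w.sum()
        freq[probe_sel] = rng.choice(config.probe_frequencies, size=probe_sel.sum(), p=w)

    return pd.DataFrame(
        {
            "trial_index": np.arange(len(types)),
            "trial_type": types,
            "frequency": freq,
            "iti": rng.uniform(*config.iti_range, size=len(types)),
        }
    )


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(
    schedule: pd.DataFrame, agent: AgentParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Attach outcomes, lick flags, response times and lick frames to a schedule.

    Licks are Bernoulli draws from the agent's psychometric function; UR trials
    (water with no stimulus) are always licked because the valve sound cues the
    animal.  Outcomes follow the task contingencies: go -> hit/miss,
    no-go -> CR/FA, probe -> PL/PNL; RO and UR keep their own labels.
    """
    if "outcome" in schedule.columns:
        raise ValueError("schedule already has outcomes")
    out = schedule.copy()
    freq = out["frequency"].to_numpy(dtype=float)
    has_stim = ~np.isnan(freq)
    if np.any((freq[has_stim] < 200.0) | (freq[has_stim] > 600.0)):
        raise ValueError("stimulus frequencies must lie within [200, 600] Hz")

    p = np.zeros(len(out))
    p[has_stim] = agent.lick_probability(freq[has_stim])
    lick = rng.random(len(out)) < p
    lick[out["trial_type"].to_numpy() == "UR"] = True
    p[~has_stim] = 1.0

    ttype = out["trial_type"].to_numpy()
    outcome = np.empty(len(out), dtype=object)
    outcome[(ttype == "go") & lick] = "hit"
    outcome[(ttype == "go") & ~lick] = "miss"
    outcome[(ttype == "no-go") & lick] = "FA"
    outcome[(ttype == "no-go") & ~lick] = "CR"
    outcome[(ttype == "probe") & lick] = "PL"
    outcome[(ttype == "probe") & ~lick] = "PNL"
    outcome[ttype == "RO"] = "RO"
    outcome[ttype == "UR"] = "UR"

    rt = np.full(len(out), np.nan)
    n_lick = int(lick.sum())
    rt[lick] = np.maximum(
        agent.rt_floor, rng.normal(agent.response_time_mean, agent.response_time_sd, size=n_lick)
    )
    lick_frame = np.full(len(out), -1)
    lick_frame[lick] = np.minimum(
        N_FRAMES - 1, ONSET_INDEX + np.round(rt[lick] * FRAME_RATE).astype(int)
    )

    out["outcome"] = outcome
    out["lick"] = lick
    out["p_lick"] = p
    out["response_time"] = rt
    out["lick_frame"] = lick_frame
    return out


# ---------------------------------------------------------------------------
# calcium population
# ---------------------------------------------------------------------------

def _calcium_kernel(rise: float, decay: float, n: int = 60) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalised, sampled at 30 fps."""
    t = np.arange(1, n + 1) / FRAME_RATE
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    return k / peak if peak > 0 else k


def synthesize_population(
    schedule: pd.DataFrame,
    spec: PopulationSpec,
    rng: np.random.Generator,
    session_id: str = "s0",
    mouse_id: str = "m0",
    day: int = 1,
) -> PopulationRecording:
    """Build a (n_neurons, 120, n_trials) recording with planted go/lick neurons.

    Go neurons respond after stimulus onset with an amplitude that grows with
    frequency (probit tuning toward 600 Hz), scaled by a per-trial gain whose
    dispersion is ``gain_variability`` (inflated at ambiguous frequencies) and
    which co-varies with the lick decision through ``choice_coupling``.  Lick
    neurons respond after the lick frame on every licked trial, including FA
    and UR.  Everything sits on additive Gaussian noise; the 1-s pre-stimulus
    baseline contains noise only.
    """
    if "outcome" not in schedule.columns:
        raise ValueError("schedule must carry outcomes; run simulate_behavior first")
    n, t = spec.n_neurons, len(schedule)
    traces = (
        spec.noise_sd * rng.standard_normal((n, N_FRAMES, t))
        if spec.noise_sd > 0
        else np.zeros((n, N_FRAMES, t))
    )

    perm = rng.permutation(n)
    n_go = int(round(spec.frac_go_neurons * n))
    n_lick = int(round(spec.frac_lick_neurons * n))
    go_idx = perm[:n_go]
    lick_idx = perm[n_go : n_go + n_lick]
    is_go = np.zeros(n, dtype=bool)
    is_go[go_idx] = True
    is_lick = np.zeros(n, dtype=bool)
    is_lick[lick_idx] = True

    ker = _calcium_kernel(spec.kernel_rise, spec.kernel_decay)
    klen = len(ker)

    freq = schedule["frequency"].to_numpy(dtype=float)
    lick = schedule["lick"].to_numpy(dtype=bool)
    p_lick = schedule.get("p_lick", pd.Series(np.full(t, 0.5))).to_numpy(dtype=float)
    has_stim = ~np.isnan(freq)

    if n_go:
        tuning = np.zeros(t)
        tuning[has_stim] = norm.cdf((freq[has_stim] - spec.tuning_center) / spec.tuning_width)
        ambiguous = np.isin(freq, np.asarray(spec.ambiguous_frequencies, dtype=float))
        gain_sd = spec.gain_variability * np.where(ambiguous, spec.ambiguity_gain_factor, 1.0)
        shift = np.where(has_stim, spec.choice_coupling * (lick.astype(float) - p_lick), 0.0)
        gain = np.clip(1.0 + shift + gain_sd * rng.standard_normal(t), 0.0, None)
        amp = spec.response_amplitude * np.exp(rng.normal(0.0, spec.amplitude_cv, size=n_go))
        signal = tuning * gain * has_stim  # per-trial scalar
        start = ONSET_INDEX + 1
        span = min(klen, N_FRAMES - start)
        traces[go_idx, start : start + span, :] += (
            amp[:, None, None] * ker[None, :span, None] * signal[None, None, :]
        )

    if n_lick:
        amp_l = spec.lick_amplitude * np.exp(rng.normal(0.0, spec.amplitude_cv, size=n_lick))
        for j in np.flatnonzero(lick):
            lf = int(schedule["lick_frame"].iloc[j])
            start = lf + 1
            if start >= N_FRAMES:
                continue
            span = min(klen, N_FRAMES - start)
            g = max(0.0, 1.0 + spec.gain_variability * rng.standard_normal())
            traces[lick_idx, start : start + span, j] += (
                amp_l[:, None] * ker[None, :span] * g
            )

    neuron_ids = [f"{session_id}_n{i:04d}" for i in range(n)]
    return PopulationRecording(
        traces=traces,
        trial_table=schedule.reset_index(drop=True).assign(
            session_id=session_id, mouse_id=mouse_id, day=day
        ),
        neuron_ids=neuron_ids,
        session_id=session_id,
        mouse_id=mouse_id,
        day=day,
        ground_truth={"go_neurons": is_go, "lick_neurons": is_lick},
    )


# ---------------------------------------------------------------------------
# paw trajectories
# ---------------------------------------------------------------------------

def simulate_paw(
    schedule: pd.DataFrame,
    premove_prob: float,
    rng: np.random.Generator,
    jitter_px: float = 4.0,
    excursion_px: tuple = (70.0, 120.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial paw coordinates at 160 samples/s plus ground-truth premove flags.

    With probability ``premove_prob`` a trial receives a smooth x-excursion of
    more than 60 px inside the 0.5-1.0 s pre-stimulus window; all other motion
    is white jitter bounded by ``jitter_px``.
    """
    if not (0.0 <= premove_prob <= 1.0):
        raise ValueError("premove_prob must lie in [0, 1]")
    t = len(schedule)
    n_samp = int(round(4.0 * PAW_FPS))
    coords = rng.uniform(-jitter_px, jitter_px, size=(t, n_samp, 2))
    flags = rng.random(t) < premove_prob
    w0, w1 = int(0.5 * PAW_FPS), int(1.0 * PAW_FPS)
    for j in np.flatnonzero(flags):
        amp = rng.uniform(*excursion_px)
        width = int(0.2 * PAW_FPS)
        c0 = int(rng.integers(w0, w1 - width))
        bump = amp * np.sin(np.linspace(0.0, np.pi, width))
        coords[j, c0 : c0 + width, 0] += bump
    return coords, flags


# ---------------------------------------------------------------------------
# whole sessions and studies
# ---------------------------------------------------------------------------

def simulate_session(
    task: TaskConfig,
    agent: AgentParams,
    pop: PopulationSpec,
    rng: np.random.Generator,
    premove_prob: float = 0.05,
    session_id: str = "s0",
    mouse_id: str = "m0",
    day: int = 1,
) -> PopulationRecording:
    """Schedule -> behavior -> paw -> population for one session."""
    sched = simulate_behavior(generate_schedule(task, rng), agent, rng)
    paw, flags = simulate_paw(sched, premove_prob, rng)
    sched["premovement_true"] = flags
    rec = synthesize_population(sched, pop, rng, session_id=session_id, mouse_id=mouse_id, day=day)
    rec.paw = paw
    return rec


def simulate_study(
    n_days: int = 8,
    trials_per_day: int = 200,
    neurons_mean: int = 150,
    mouse_id: str = "m0",
    seed: int | np.random.Generator = 0,
    interruption_day: int | None = 6,
    interruption_factor: float = 2.2,
    task: TaskConfig | None = None,
    pop_overrides: dict | None = None,
) -> list[PopulationRecording]:
    """A learning curve over ``n_days`` imaging sessions for one simulated mouse.

    Per day the agent's psychometric slope rises and its lapse rate falls
    (naive -> expert), the planted go/lick neuron fractions grow (3.6% -> 12.2%
    and 1.1% -> 15.9%), premovement becomes rarer, and the per-trial gain
    dispersion shrinks, so decoding gets easier with learning.  On the
    interruption day (a weekend pause, default day 6) gain dispersion is
    transiently re-inflated.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    task = task or TaskConfig(n_trials=trials_per_day)
    recs = []
    for day in range(1, n_days + 1):
        s = (day - 1) / max(1, n_days - 1)
        over = dict(pop_overrides or {})
        gv = 0.5 - 0.3 * s
        noise = over.pop("noise_sd", 1.0)
        if interruption_day is not None and day == interruption_day:
            # weekend pause: noisier, more variable population responses
            # without any change to the agent's behavior
            gv *= interruption_factor
            noise *= interruption_factor
        n_neurons = over.pop("n_neurons", None)
        if n_neurons is None:
            n_neurons = int(rng.integers(int(0.8 * neurons_mean), int(1.2 * neurons_mean) + 1))
        pop = PopulationSpec(
            n_neurons=n_neurons,
            frac_go_neurons=over.pop("frac_go_neurons", 0.036 + (0.122 - 0.036) * s),
            frac_lick_neurons=over.pop("frac_lick_neurons", 0.011 + (0.159 - 0.011) * s),
            gain_variability=over.pop("gain_variability", gv),
            noise_sd=noise,
            **over,
        )
        rec = simulate_session(
            task,
            AgentParams.for_stage(s),
            pop,
            rng,
            premove_prob=0.15 - 0.13 * s,
            session_id=f"{mouse_id}_d{day}",
            mouse_id=mouse_id,
            day=day,
        )
        recs.append(rec)
    return recs
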