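"""Synthetic accelerometer sessions, week-long 24/7 recordings and detectors.

The generator emulates the statistical structure of the benchmark FOG
datasets so that every evaluation stage can be exercised without the real
recordings or trained models:

* activity is a semi-Markov chain over {rest, stand, gait initiation,
  walk, turn} with explicit log-normal dwell times;
* FOG episodes are injected only within their triggering context (start
  hesitation at gait initiation, turn FOG in turns, walking FOG during
  straight walking), with log-normal durations whose class means follow
  the benchmark dataset's event tables (e.g. turn episodes average
  ~9.7 s = 469.1 min over 2887 events);
* a configurable fraction of episodes is akinetic (near-motionless) —
  5.6% in the lab-protocol dialect, 29.3% in the home-protocol dialect;
* the acceleration signal is spectral, not biomechanical: walking is a
  step-frequency fundamental plus harmonic, trembling FOG is band-limited
  noise in the 3-8 Hz freeze band, akinesia and rest are noise floor;
* week-long recordings place walking bouts by clock hour and scale FOG
  trigger probabilities by a 24-bin hour-of-day intensity profile
  (freezer default peaks near 07:00 and 22:00, with sparse short night
  bouts so the nocturnal reference %TF is well-defined);
* ``simulate_detector`` turns a label series into per-class confidence
  scores of controllable quality, standing in for trained models.

All randomness is derived from (seed, subject_id, day) so cohorts are
reproducible under parallel generation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_io import Dialect, LabelSeries, Recording, ScoreSeries, WalkingBouts
from .errors import ValidationError

# activity-state codes
REST, STAND, INIT, WALK, TURN = 0, 1, 2, 3, 4
STATE_NAMES = {REST: "rest", STAND: "stand", INIT: "gait_initiation",
               WALK: "walk", TURN: "turn"}
# FOG class per triggering state
_STATE_CLASS = {INIT: "start_hesitation", TURN: "turn", WALK: "walking"}
_CLASS_IDX = {"start_hesitation": 0, "turn": 1, "walking": 2, "notype": 3}


def default_hourly_intensity(peaks: Sequence[int] = (7, 22), base: float = 1.0,
                             peak_gain: float = 2.5, night: float = 0.3,
                             daytime: Sequence[int] = tuple(range(7, 23)),
                             ) -> np.ndarray:
    """Hour-of-day FOG trigger multipliers: daytime base, morning/evening peaks.

    ``night=0`` yields a purely daytime effect (useful when the analysis
    should find group differences only at configured daytime hours).
    """
    v = np.full(24, float(night))
    for h in daytime:
        v[h] = base
    for p in peaks:
        v[p] = peak_gain
    return v


def default_bout_rate(day_rate: float = 5.0, night_rate: float = 0.5,
                      daytime: Sequence[int] = tuple(range(7, 23))) -> np.ndarray:
    """Expected walking bouts per clock hour (sparse bathroom walks at night)."""
    v = np.full(24, float(night_rate))
    for h in daytime:
        v[h] = day_rate
    return v


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Dwell means/log-sigmas and episode-duration parameters are log-normal;
    ``episode_duration`` class means follow the benchmark event tables
    (turn ~9.7 s, start hesitation ~15 s, walking ~5.7 s on average).
    ``propensity_shape`` is the gamma shape of the unit-mean per-subject
    FOG propensity multiplier; 0.3 makes the realized freezer vs.
    non-freezer standardized difference in daily %TF approximately 0.7
    (a moderate effect) at cohort sizes 45 vs. 19.
    """

    seed: int = 0
    dialect: Dialect = Dialect.tdcsfog
    sampling_rate: Optional[float] = None      # None -> dialect default
    session_duration_s: float = 300.0
    state_dwell: dict = field(default_factory=lambda: {
        REST: (30.0, 0.5), STAND: (8.0, 0.5), INIT: (2.5, 0.3),
        WALK: (20.0, 0.6), TURN: (3.5, 0.3)})
    fog_trigger_probs: dict = field(default_factory=lambda: {
        "turn": 0.30, "walk": 0.05, "gait_initiation": 0.12})
    episode_duration: dict = field(default_factory=lambda: {
        "start_hesitation": (15.0, 0.6), "turn": (9.7, 0.6),
        "walking": (5.7, 0.6)})
    akinetic_fraction: Optional[float] = None  # None -> dialect default
    notype_fraction: float = 0.0
    walk_step_freq: float = 1.8
    tremble_band: tuple = (3.0, 8.0)
    walk_amp: float = 2.0
    tremble_amp: float = 1.2
    noise_sd: float = 0.15
    hourly_intensity: np.ndarray = field(default_factory=default_hourly_intensity)
    bout_rate_per_hour: np.ndarray = field(default_factory=default_bout_rate)
    bout_duration: tuple = (60.0, 0.5)
    group: str = "freezer"
    propensity_shape: float = 0.3
    daily_trigger_scale: float = 0.25
    start_clock: datetime = field(default_factory=lambda: datetime(2024, 3, 4, 0, 0, 0))
    synthesize_acc: bool = True

    def __post_init__(self):
        self.dialect = Dialect(self.dialect)
        if self.sampling_rate is None:
            self.sampling_rate = {Dialect.tdcsfog: 128.0, Dialect.defog: 100.0,
                                  Dialect.daily: 100.0}[self.dialect]
        if self.akinetic_fraction is None:
            self.akinetic_fraction = 0.056 if self.dialect == Dialect.tdcsfog else 0.293
        self.hourly_intensity = np.asarray(self.hourly_intensity, dtype=float)
        self.bout_rate_per_hour = np.asarray(self.bout_rate_per_hour, dtype=float)
        for name, p in self.fog_trigger_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"trigger probability for {name!r} outside [0, 1]")
        if (self.hourly_intensity < 0).any():
            raise ValidationError("hourly_intensity must be non-negative")
        for mean, _ in self.episode_duration.values():
            if mean <= 0:
                raise ValidationError("episode durations must be positive")


def _rng(*entropy) -> np.random.Generator:
    words = [zlib.crc32(e.encode()) if isinstance(e, str) else int(e)
             for e in entropy]
    return np.random.default_rng(np.random.SeedSequence(words))


def _lognormal(rng, mean: float, sigma: float) -> float:
    """Draw with the requested arithmetic mean (mu = ln(mean) - sigma^2/2)."""
    return float(rng.lognormal(np.log(mean) - sigma ** 2 / 2.0, sigma))


def subject_propensity(config: SimConfig, subject_id: str) -> float:
    """Per-subject FOG propensity multiplier (0 for non-freezers).

    Gamma with unit mean; deterministic in (seed, subject_id).
    """
    if config.group == "non_freezer":
        return 0.0
    rng = _rng(config.seed, subject_id, 997)
    k = config.propensity_shape
    return float(rng.gamma(k, 1.0 / k))


# ---------------------------------------------------------------------------
# Protocol sessions
# ---------------------------------------------------------------------------

_TRANSITIONS = {
    REST: [(STAND, 1.0)],
    STAND: [(INIT, 0.7), (REST, 0.3)],
    INIT: [(WALK, 1.0)],
    WALK: [(TURN, 0.6), (STAND, 0.4)],
    TURN: [(WALK, 0.8), (STAND, 0.2)],
}


def _next_state(rng, state: int) -> int:
    options, probs = zip(*_TRANSITIONS[state])
    return int(rng.choice(options, p=probs))


def _maybe_inject_episode(rng, config: SimConfig, state: int, dwell_n: int,
                          fs: float, trigger_scale: float = 1.0):
    """Episode (offset, length, class_idx, akinetic) within a dwell, or None."""
    cls = _STATE_CLASS.get(state)
    if cls is None or dwell_n < 2:
        return None
    key = {"start_hesitation": "gait_initiation", "turn": "turn",
           "walking": "walk"}[cls]
    p = min(config.fog_trigger_probs[key] * trigger_scale, 0.95)
    if rng.random() >= p:
        return None
    mean, sigma = config.episode_duration[cls]
    length = max(1, min(int(round(_lognormal(rng, mean, sigma) * fs)), dwell_n))
    if state == INIT:
        offset = 0  # start hesitation begins with the initiation attempt
    else:
        offset = int(rng.integers(0, dwell_n - length + 1))
    class_idx = _CLASS_IDX[cls]
    if config.notype_fraction > 0 and rng.random() < config.notype_fraction:
        class_idx = _CLASS_IDX["notype"]
    akinetic = rng.random() < config.akinetic_fraction
    return offset, length, class_idx, akinetic


def _simulate_states(rng, config: SimConfig, n_samples: int,
                     trigger_scale: float = 1.0):
    """Semi-Markov state path with injected episodes over n_samples samples.

    Returns (states, fog_class, akinetic): int arrays; fog_class is -1
    where no FOG, else a class index.
    """
    fs = config.sampling_rate
    states = np.empty(n_samples, dtype=np.int8)
    fog = np.full(n_samples, -1, dtype=np.int8)
    akinetic = np.zeros(n_samples, dtype=bool)
    pos = 0
    state = STAND
    while pos < n_samples:
        mean, sigma = config.state_dwell[state]
        dwell_n = max(1, int(round(_lognormal(rng, mean, sigma) * fs)))
        dwell_n = min(dwell_n, n_samples - pos)
        states[pos:pos + dwell_n] = state
        ep = _maybe_inject_episode(rng, config, state, dwell_n, fs, trigger_scale)
        if ep is not None:
            off, length, class_idx, akin = ep
            fog[pos + off:pos + off + length] = class_idx
            akinetic[pos + off:pos + off + length] = akin
        pos += dwell_n
        state = _next_state(rng, state)
    return states, fog, akinetic


def _labels_from_fog(fog: np.ndarray, valid=None, task=None) -> LabelSeries:
    n = len(fog)
    return LabelSeries(
        start_hesitation=fog == _CLASS_IDX["start_hesitation"],
        turn=fog == _CLASS_IDX["turn"],
        walking=fog == _CLASS_IDX["walking"],
        notype=fog == _CLASS_IDX["notype"],
        valid=np.ones(n, bool) if valid is None else valid,
        task=np.ones(n, bool) if task is None else task,
    )


def synthesize_signal(states: np.ndarray, fog: np.ndarray,
                      akinetic: np.ndarray, config: SimConfig,
                      rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Spectral surrogate acceleration for a state/episode path.

    Walking/turning: step-frequency fundamental plus first harmonic;
    trembling FOG: band-limited noise inside the freeze band; akinetic
    FOG, rest and stand: noise floor.  State boundaries are crossfaded by
    smoothing the component envelopes, so the signal is continuous.
    Returns (N, 3) m/s^2 with gravity on the vertical axis.
    """
    rng = rng or _rng(config.seed, 131)
    fs = config.sampling_rate
    n = len(states)
    t = np.arange(n) / fs
    f = config.walk_step_freq

    moving = ((states == WALK) | (states == TURN)) & (fog < 0)
    trembling = (fog >= 0) & ~akinetic

    def smooth(env):
        w = max(1, int(round(0.3 * fs)))
        if w <= 1:
            return env.astype(float)
        kernel = np.hanning(w + 2)[1:-1]
        kernel /= kernel.sum()
        return np.convolve(env.astype(float), kernel, mode="same")

    gait_env = smooth(moving)
    tremble_env = smooth(trembling)

    a = config.walk_amp
    phase = rng.uniform(0, 2 * np.pi)
    gait = np.column_stack([
        a * np.sin(2 * np.pi * f * t + phase) + 0.35 * a * np.sin(4 * np.pi * f * t + 2 * phase),
        0.45 * a * np.sin(np.pi * f * t + phase),
        0.55 * a * np.sin(2 * np.pi * f * t + phase + 0.8),
    ])

    lo, hi = config.tremble_band
    tremble = rng.standard_normal((n, 3))
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    band = (freqs >= lo) & (freqs <= hi)
    for j, scale in enumerate((1.0, 0.6, 0.8)):
        spec = np.fft.rfft(tremble[:, j])
        spec[~band] = 0.0
        x = np.fft.irfft(spec, n)
        sd = x.std()
        tremble[:, j] = (x / sd if sd > 0 else x) * config.tremble_amp * scale

    acc = (gait_env[:, None] * gait + tremble_env[:, None] * tremble
           + config.noise_sd * rng.standard_normal((n, 3)))
    acc[:, 0] += 9.80665
    return acc


def generate_protocol_session(config: SimConfig, subject_id: str = "SY01",
                              session_id: str = "sess0",
                              ) -> tuple[Recording, LabelSeries]:
    """One FOG-provoking protocol session in the configured dialect.

    Deterministic in (config.seed, subject_id, session_id).  For the
    defog dialect, a short lead-in/out is marked non-Task and a random
    block may be marked non-Valid, mimicking that dialect's masking.
    """
    if config.session_duration_s <= 0:
        raise ValidationError("session duration must be positive")
    fs = config.sampling_rate
    n = int(round(config.session_duration_s * fs))
    if n < 1:
        raise ValidationError("session too short for the sampling rate")
    rng = _rng(config.seed, subject_id, session_id)
    states, fog, akinetic = _simulate_states(rng, config, n)

    valid = np.ones(n, bool)
    task = np.ones(n, bool)
    if config.dialect == Dialect.defog:
        edge = min(int(round(5 * fs)), n // 4)
        task[:edge] = False
        task[-edge:] = False
        if rng.random() < 0.3 and n > 10:
            a = int(rng.integers(0, n - n // 10))
            valid[a:a + n // 10] = False

    labels = _labels_from_fog(fog, valid, task)
    acc = (synthesize_signal(states, fog, akinetic, config, rng)
           if config.synthesize_acc else np.zeros((n, 3)))
    rec = Recording(subject_id=subject_id, session_id=session_id,
                    dialect=config.dialect, sampling_rate=fs, acc=acc,
                    provenance={"generator": "protocol", "seed": config.seed})
    return rec, labels


# ---------------------------------------------------------------------------
# Week-long 24/7 recordings
# ---------------------------------------------------------------------------


def generate_week(config: SimConfig, subject_id: str = "SY01",
                  ) -> tuple[Recording, LabelSeries, WalkingBouts]:
    """Seven consecutive simulated days with ground-truth walking bouts.

    Bout placement follows ``bout_rate_per_hour``; FOG triggering scales
    with ``hourly_intensity[hour] * subject_propensity * daily_trigger_scale``.
    Non-freezers emit zero true FOG.  Set ``synthesize_acc=False`` for
    label-level cohort studies where the waveform is not needed.
    """
    if config.start_clock is None:
        raise ValidationError("generate_week requires start_clock")
    fs = config.sampling_rate
    day_n = int(round(86400 * fs))
    n = 7 * day_n
    fog = np.full(n, -1, dtype=np.int8)
    states = np.full(n, REST, dtype=np.int8)
    akinetic = np.zeros(n, dtype=bool)
    intervals: list[tuple[int, int]] = []
    propensity = subject_propensity(config, subject_id)

    walk_dwell = (12.0, 0.5)
    for day in range(7):
        rng = _rng(config.seed, subject_id, day)
        for hour in range(24):
            n_bouts = rng.poisson(config.bout_rate_per_hour[hour])
            if n_bouts == 0:
                continue
            trigger_scale = (config.hourly_intensity[hour] * propensity
                             * config.daily_trigger_scale)
            hour_start = day * day_n + int(round(hour * 3600 * fs))
            durations = [_lognormal(rng, *config.bout_duration) for _ in range(n_bouts)]
            starts = np.sort(rng.uniform(0, 3600, size=n_bouts))
            cursor = 0.0
            for s0, dur in zip(starts, durations):
                s0 = max(s0, cursor)
                if s0 + dur > 3600:
                    dur = 3600 - s0
                if dur < 5.0:
                    continue
                cursor = s0 + dur + 2.0
                a = hour_start + int(round(s0 * fs))
                b = min(a + max(1, int(round(dur * fs))), n)
                if a >= b:
                    continue
                intervals.append((a, b))
                _fill_bout(rng, config, states, fog, akinetic, a, b,
                           walk_dwell, trigger_scale)

    labels = _labels_from_fog(fog)
    if config.synthesize_acc:
        acc = synthesize_signal(states, fog, akinetic, config,
                                _rng(config.seed, subject_id, 131))
    else:
        acc = np.zeros((n, 3))
    rec = Recording(subject_id=subject_id, session_id=f"{subject_id}_week",
                    dialect=Dialect.daily, sampling_rate=fs, acc=acc,
                    start_clock=config.start_clock,
                    provenance={"generator": "week", "seed": config.seed,
                                "propensity": propensity})
    return rec, labels, WalkingBouts(intervals)


def _fill_bout(rng, config, states, fog, akinetic, a: int, b: int,
               walk_dwell, trigger_scale: float) -> None:
    """Populate one walking bout: initiation, then alternating walk/turn."""
    fs = config.sampling_rate
    pos = a
    init_n = min(max(1, int(round(2.0 * fs))), b - pos)
    states[pos:pos + init_n] = INIT
    ep = _maybe_inject_episode(rng, config, INIT, init_n, fs, trigger_scale)
    if ep is not None:
        off, length, class_idx, akin = ep
        fog[pos + off:pos + off + length] = class_idx
        akinetic[pos + off:pos + off + length] = akin
    pos += init_n
    state = WALK
    while pos < b:
        mean, sigma = walk_dwell if state == WALK else config.state_dwell[TURN]
        dwell_n = max(1, min(int(round(_lognormal(rng, mean, sigma) * fs)), b - pos))
        states[pos:pos + dwell_n] = state
        ep = _maybe_inject_episode(rng, config, state, dwell_n, fs, trigger_scale)
        if ep is not None:
            off, length, class_idx, akin = ep
            fog[pos + off:pos + off + length] = class_idx
            akinetic[pos + off:pos + off + length] = akin
        pos += dwell_n
        state = TURN if state == WALK else WALK


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def cohort_manifest(config: SimConfig, n_freezers: int = 45,
                    n_non_freezers: int = 19) -> pd.DataFrame:
    """Subject manifest (id, group, severity questionnaire score).

    Freezer severity scores are rank-matched to the subject's latent FOG
    propensity (center 20, spread ~4, clipped to 10-28), so a median split
    produces genuinely ordered moderate vs. severe subgroups; non-freezers
    score 0.
    """
    from scipy import stats as _st

    rows = []
    k = config.propensity_shape
    for i in range(n_freezers):
        sid = f"F{i:03d}"
        prop = subject_propensity(replace(config, group="freezer"), sid)
        z = _st.norm.ppf(np.clip(_st.gamma.cdf(prop, k, scale=1.0 / k),
                                 1e-9, 1 - 1e-9))
        rows.append({"subject_id": sid, "group": "freezer",
                     "nfogq": int(np.clip(round(20 + 4.0 * z), 10, 28))})
    for i in range(n_non_freezers):
        rows.append({"subject_id": f"N{i:03d}", "group": "non_freezer", "nfogq": 0})
    return pd.DataFrame(rows)


def generate_cohort(config: SimConfig, n_freezers: int = 45,
                    n_non_freezers: int = 19):
    """Yield (subject_id, group, Recording, LabelSeries, WalkingBouts) per subject."""
    manifest = cohort_manifest(config, n_freezers, n_non_freezers)
    for row in manifest.itertuples(index=False):
        cfg = replace(config, group=row.group)
        rec, labels, bouts = generate_week(cfg, subject_id=row.subject_id)
        yield row.subject_id, row.group, rec, labels, bouts


# ---------------------------------------------------------------------------
# Simulated detectors
# ---------------------------------------------------------------------------


def _jitter_episodes(ind: np.ndarray, jitter_samples: float,
                     rng: np.random.Generator) -> np.ndarray:
    if jitter_samples <= 0 or not ind.any():
        return ind.copy()
    out = np.zeros_like(ind)
    edges = np.diff(np.r_[0, ind.astype(np.int8), 0])
    for a, b in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1)):
        a2 = int(np.clip(a + round(rng.normal(0, jitter_samples)), 0, len(ind)))
        b2 = int(np.clip(b + round(rng.normal(0, jitter_samples)), 0, len(ind)))
        if b2 > a2:
            out[a2:b2] = True
    return out


def simulate_detector(labels: LabelSeries, quality: float,
                      fp_rate: float = 0.0, boundary_jitter_s: float = 0.0,
                      seed: int = 0, sampling_rate: float = 100.0) -> ScoreSeries:
    """Per-class confidence scores of controllable quality.

    scores = logistic(quality * indicator + standard normal noise), where
    the indicator is the class channel after boundary jitter and insertion
    of false-positive bursts (``fp_rate`` = expected burst starts per
    second, burst length log-normal with 2 s mean).  quality 0 is an
    uninformative detector; large quality approaches a perfect ranking.
    """
    if quality < 0:
        raise ValidationError("detector quality must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 202]))
    n = len(labels)
    channels = {}
    for fog_class in ("start_hesitation", "turn", "walking"):
        ind = labels.class_channel(fog_class)
        ind = _jitter_episodes(ind, boundary_jitter_s * sampling_rate, rng)
        if fp_rate > 0:
            starts = np.flatnonzero(rng.random(n) < fp_rate / sampling_rate)
            for s0 in starts:
                length = max(1, int(round(_lognormal(rng, 2.0, 0.5) * sampling_rate)))
                ind[s0:s0 + length] = True
        channels[fog_class] = expit(quality * ind.astype(float)
                                    + rng.standard_normal(n))
    return ScoreSeries(**channels)
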