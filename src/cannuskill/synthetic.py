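"""Synthetic cannulation cohort generator.

The sensor dataset this package analyses (needle-tip trajectories from a
simulated arteriovenous-fistula cannulation task) is not publicly
distributable, so this module generates cohorts with the statistical
structure the analysis assumes:

* movements are concatenations of minimum-jerk submovements — the canonical
  maximally smooth point-to-point motion — separated by stationary pauses;
  lower-skill performers produce more submovements and longer pauses
  (intermittency), the signature the smoothness metrics are built to detect;
* additive sensor noise calibrated so the mean absolute height of its local
  extrema matches a configurable target (0.06 mm by default, matching the
  electromagnetic tracker's observed peak noise);
* a skin-crossing entry event followed by a flashback (in-needle LED)
  channel whose onset delay and interruption probability worsen with lower
  skill, so the flash-ratio outcome tracks latent skill;
* participant-level indicators: expert ratings (GRS) generated as
  discretised noisy latent skill, and years of experience with configurable
  — by default weak — correlation to skill.

Every participant carries one latent skill scalar in [0, 1]; each trial
perturbs it with trial-level jitter that drives both the kinematics and the
flashback outcome, so the outcome metric shares trial-level variance with
the process metrics while the observer and experience indicators do not.
Generation is a pure function of (spec, seed).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .io import GRS_CATEGORIES, KinematicSeries, TrialMeta

__all__ = [
    "EffectMap",
    "CohortSpec",
    "Submovement",
    "SubmovementPlan",
    "Cohort",
    "min_jerk_trajectory",
    "min_jerk_profile",
    "compose_trial",
    "even_split_plan",
    "add_sensor_noise",
    "simulate_flash",
    "simulate_trial",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# specification objects


@dataclasses.dataclass
class EffectMap:
    """Coefficients linking latent skill to observable structure.

    All skill effects are monotone in the latent scalar ``s`` ∈ [0, 1]
    (1 = most skilled).  After insertion the performer settles the needle;
    skill decides both the length and the texture of that phase.  Time
    spent settling shrinks from roughly ``1.25·adjust_budget_s`` at the
    bottom of the scale to a quarter of it at the top, and its texture
    shifts from many quick jabs (duration ``correction_fast_s``, up to
    ``1 + submovement_rate`` of them) separated by arrests to one or two
    slow deliberate corrections (``correction_slow_s``) — many brief sharp
    submovements being the kinematic signature of intermittency.  The
    flashback onset delay is
    ``flash_delay_base_s + flash_delay_slope_s·(1−s)`` and each
    ``flash_chunk_s`` interval after onset goes dark independently with
    probability ``flash_interrupt_coef·(1−s)``.  ``trial_skill_sd`` is the
    SD of trial-level jitter around participant skill.  ``exp_skill_corr``
    is the target correlation between experience and skill (the study this
    emulates found experience nearly uninformative, so the default is low).

    ``pace_cv`` and ``trial_pace_cv`` give each participant (and each trial)
    a lognormal duration multiplier *independent of skill*: skilled
    performers can still be slow and deliberate.  Pace stretches every
    submovement, pause and hold uniformly, which leaves the dimensionless
    smoothness metrics untouched on clean data — but not their sensor-noise
    floor, which scales with duration.
    """

    submovement_rate: float = 9.0
    adjust_budget_s: float = 5.5
    correction_fast_s: float = 0.3
    correction_slow_s: float = 1.2
    flash_delay_base_s: float = 0.2
    flash_delay_slope_s: float = 1.5
    flash_interrupt_coef: float = 0.5
    flash_chunk_s: float = 0.25
    grs_noise_sd: float = 0.15
    grs_rater_sd: float = 0.3
    exp_skill_corr: float = 0.15
    trial_skill_sd: float = 0.08
    pace_cv: float = 0.2
    trial_pace_cv: float = 0.1
    exp_mean_years: float = 11.0
    exp_sd_years: float = 8.6
    exp_max_years: float = 38.0

    def validate(self) -> None:
        if not 0.0 <= self.flash_interrupt_coef <= 1.0:
            raise ValueError("flash_interrupt_coef must lie in [0, 1]")
        if not -1.0 <= self.exp_skill_corr <= 1.0:
            raise ValueError("exp_skill_corr must lie in [-1, 1]")
        if not 0 < self.correction_fast_s <= self.correction_slow_s:
            raise ValueError("need 0 < correction_fast_s <= correction_slow_s")
        for name in ("submovement_rate", "adjust_budget_s",
                     "flash_delay_base_s",
                     "flash_delay_slope_s", "flash_chunk_s", "grs_noise_sd",
                     "grs_rater_sd",
                     "trial_skill_sd", "pace_cv", "trial_pace_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclasses.dataclass
class CohortSpec:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror the emulated study: 52 participants performing four
    attempts on each of four fistulas (16 trials each) at 100 Hz, sensor
    noise with 0.06 mm mean peak height, and a latent-skill distribution
    centred mid-scale.
    """

    n_participants: int = 52
    trials_per_participant: int = 16
    fs: float = 100.0
    skill_mean: float = 0.5
    skill_sd: float = 0.2
    noise_peak_mean: float = 0.06
    noise_peak_cv: float = 1.0
    noise_bandwidth_hz: float = 15.0
    skin_z: float = 100.0
    effects: EffectMap = dataclasses.field(default_factory=EffectMap)

    def validate(self) -> None:
        if self.trials_per_participant < 1:
            raise ValueError("trials_per_participant must be >= 1")
        if self.noise_peak_mean < 0:
            raise ValueError("noise_peak_mean must be >= 0")
        if self.noise_peak_cv < 0:
            raise ValueError("noise_peak_cv must be >= 0")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.effects.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        effects = d.pop("effects", {})
        spec = cls(**d, effects=EffectMap(**effects))
        spec.validate()
        return spec


@dataclasses.dataclass
class Submovement:
    start_time: float
    duration: float
    displacement: np.ndarray  # 3-vector, mm

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float).reshape(3)
        if self.duration <= 0:
            raise ValueError("submovement duration must be positive")


@dataclasses.dataclass
class SubmovementPlan:
    """Chronologically ordered, non-overlapping minimum-jerk segments.

    Gaps between consecutive segments are stationary pauses (exactly
    constant position before noise injection).  ``tail_hold_s`` appends a
    terminal hold after the last segment.
    """

    start: np.ndarray  # initial position, mm
    segments: list
    tail_hold_s: float = 0.0

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float).reshape(3)
        prev_end = 0.0
        for seg in self.segments:
            if seg.start_time < prev_end - 1e-12:
                raise ValueError("submovement segments overlap or are out of order")
            prev_end = seg.start_time + seg.duration
        if not self.segments:
            raise ValueError("plan needs at least one segment")

    @property
    def total_time(self) -> float:
        last = self.segments[-1]
        return last.start_time + last.duration + self.tail_hold_s


@dataclasses.dataclass
class Cohort:
    """A generated cohort: trials plus the participant-level ground truth.

    ``participants`` includes the latent skill scalar — unobservable in a
    real study, kept here for validation — alongside the observable
    indicators.
    """

    spec: CohortSpec
    seed: int
    trials: list  # of (KinematicSeries, TrialMeta)
    participants: pd.DataFrame


# ---------------------------------------------------------------------------
# trajectory primitives


def min_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalised minimum-jerk displacement profile 10τ³ − 15τ⁴ + 6τ⁵."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def min_jerk_trajectory(p0, p1, duration: float, fs: float) -> KinematicSeries:
    """Single minimum-jerk point-to-point movement, sampled at ``fs``.

    The quintic ``p(τ) = p0 + (p1−p0)(10τ³ − 15τ⁴ + 6τ⁵)`` with τ = t/T is
    the unique trajectory minimising integrated squared jerk under rest-to-
    rest boundary conditions (zero velocity and acceleration at both ends).
    Peak speed is 1.875·|p1−p0|/T at the midpoint.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if fs * duration < 10:
        raise ValueError("need at least 10 samples: increase duration or fs")
    p0 = np.asarray(p0, dtype=float).reshape(3)
    p1 = np.asarray(p1, dtype=float).reshape(3)
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs
    q = min_jerk_profile(t / duration)
    pos = p0[None, :] + q[:, None] * (p1 - p0)[None, :]
    return KinematicSeries(
        t=t, x=pos[:, 0], y=pos[:, 1], z=pos[:, 2],
        flash=np.zeros(n, dtype=np.int8), fs=fs,
    )


def compose_trial(plan: SubmovementPlan, fs: float) -> KinematicSeries:
    """Concatenate minimum-jerk segments and stationary pauses into one trial.

    Position is continuous at every junction: each segment starts where the
    previous one ended, and pause samples hold position exactly constant.
    """
    total = plan.total_time
    n = int(round(total * fs)) + 1
    t = np.arange(n) / fs
    pos = np.tile(plan.start, (n, 1))
    for seg in plan.segments:
        q = min_jerk_profile((t - seg.start_time) / seg.duration)
        pos += q[:, None] * seg.displacement[None, :]
    return KinematicSeries(
        t=t, x=pos[:, 0], y=pos[:, 1], z=pos[:, 2],
        flash=np.zeros(n, dtype=np.int8), fs=fs,
    )


def even_split_plan(
    start,
    displacement,
    n_segments: int,
    total_time: float,
    pause_s: float = 0.0,
) -> SubmovementPlan:
    """Split one movement into ``n_segments`` equal collinear submovements.

    Total displacement and total time are held fixed (pauses included), so
    smoothness metrics across a ladder of ``n_segments`` values compare
    like-for-like: more submovements in the same envelope = more
    intermittent = less smooth.
    """
    displacement = np.asarray(displacement, dtype=float).reshape(3)
    move_time = total_time - (n_segments - 1) * pause_s
    if move_time <= 0:
        raise ValueError("pauses exceed the total time budget")
    seg_dur = move_time / n_segments
    segments = []
    t0 = 0.0
    for _ in range(n_segments):
        segments.append(Submovement(t0, seg_dur, displacement / n_segments))
        t0 += seg_dur + pause_s
    return SubmovementPlan(start=start, segments=segments)


# ---------------------------------------------------------------------------
# noise


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def add_sensor_noise(
    series: KinematicSeries,
    peak_mean: float,
    rng_seed,
    bandwidth_hz: float = 15.0,
) -> KinematicSeries:
    """Add band-limited sensor noise calibrated by its local-extrema mean.

    White Gaussian noise is low-pass filtered (4th-order zero-phase
    Butterworth at ``bandwidth_hz``) and rescaled per axis so the mean
    absolute height of its local extrema equals ``peak_mean`` exactly for
    this realisation.  The extrema statistic is the one observable the
    emulated tracker noise is characterised by; the spectrum (bandwidth) is
    a free choice and deliberately configurable.  Deterministic under a
    fixed seed; ``peak_mean = 0`` returns the input unchanged.
    """
    if peak_mean < 0:
        raise ValueError("peak_mean must be >= 0")
    if peak_mean == 0.0:
        return series.replace()
    rng = _as_rng(rng_seed)
    n = len(series)
    noisy = {}
    sos = None
    if bandwidth_hz < series.fs / 2:
        sos = butter(4, bandwidth_hz, fs=series.fs, output="sos")
    for name in ("x", "y", "z"):
        white = rng.standard_normal(n)
        noise = sosfiltfilt(sos, white) if sos is not None else white
        interior = noise[1:-1]
        is_ext = (interior - noise[:-2]) * (interior - noise[2:]) > 0
        ext = np.abs(interior[is_ext])
        if ext.size == 0:
            raise ValueError("record too short to calibrate noise extrema")
        noise *= peak_mean / ext.mean()
        noisy[name] = getattr(series, name) + noise
    return series.replace(**noisy)


# ---------------------------------------------------------------------------
# flashback channel


def simulate_flash(
    series: KinematicSeries,
    skin_z: float,
    skill: float,
    rng_seed,
    effects: EffectMap | None = None,
) -> tuple[np.ndarray, float | None]:
    """Simulate the in-needle LED channel for a trial.

    Flashback begins a skill-dependent delay after the needle tip first
    crosses below ``skin_z`` and is then interrupted chunk-wise with
    per-interval probability ``flash_interrupt_coef·(1−skill)``: higher
    skill gives stochastically higher flash ratios, skill 1 an
    uninterrupted flash to the end of the record.

    Returns the flash channel and the entry time (``None`` when the needle
    never crossed the skin, in which case the channel is all zeros).
    """
    if not 0.0 <= skill <= 1.0:
        raise ValueError("skill must lie in [0, 1]")
    effects = effects or EffectMap()
    rng = _as_rng(rng_seed)
    n = len(series)
    flash = np.zeros(n, dtype=np.int8)
    below = np.flatnonzero(series.z < skin_z)
    if below.size == 0:
        return flash, None
    t_entry = float(series.t[below[0]])
    delay = effects.flash_delay_base_s + effects.flash_delay_slope_s * (1.0 - skill)
    onset = t_entry + delay
    t_end = float(series.t[-1])
    if onset >= t_end:
        return flash, t_entry
    p_off = min(max(effects.flash_interrupt_coef * (1.0 - skill), 0.0), 1.0)
    chunk = max(effects.flash_chunk_s, 1.0 / series.fs)
    edges = np.arange(onset, t_end + chunk, chunk)
    active = series.t >= onset
    on = np.ones(n, dtype=bool)
    for k in range(len(edges) - 1):
        if rng.random() < p_off:
            on &= ~((series.t >= edges[k]) & (series.t < edges[k + 1]))
    flash[active & on] = 1
    return flash, t_entry


# ---------------------------------------------------------------------------
# trials and cohorts


def simulate_trial(
    skill: float,
    spec: CohortSpec,
    rng_seed,
    fistula_id: int = 1,
    pace: float = 1.0,
) -> KinematicSeries:
    """One synthetic cannulation trial for a performer of given trial skill.

    The trial is: a short pre-entry hold above the skin, an insertion
    submovement crossing the skin into the fistula, a skill-dependent number
    of corrective submovements separated by pauses, and a terminal hold
    (levelling out).  ``pace`` multiplies every duration (skill-independent
    tempo).  Sensor noise and the flashback channel are then added.
    """
    rng = _as_rng(rng_seed)
    eff = spec.effects
    s = float(np.clip(skill, 0.0, 1.0))
    pace = float(pace)
    if pace <= 0:
        raise ValueError("pace must be positive")
    # fistulas sit at distinct lateral offsets on the simulated forearm
    fistula_xy = {1: (-30.0, 0.0), 2: (-10.0, 0.0), 3: (10.0, 0.0), 4: (30.0, 0.0)}
    fx, fy = fistula_xy.get(int(fistula_id), (0.0, 0.0))
    z0 = spec.skin_z + 15.0 + rng.uniform(0.0, 10.0)
    start = np.array([fx + rng.normal(0, 4.0), fy + rng.normal(0, 4.0), z0])

    segments = []
    t0 = (0.3 + 0.2 * rng.random()) * pace  # pre-entry hold
    depth = 4.0 + rng.uniform(0.0, 2.0)
    # the insertion thrust is swift for everyone; skill expresses as the
    # texture of the adjustment phase, not as tempo
    ins_dur = (0.7 + rng.uniform(-0.1, 0.1)) * pace
    ins_disp = np.array(
        [rng.normal(0, 4.0), rng.normal(0, 4.0), -(z0 - spec.skin_z) - depth]
    )
    segments.append(Submovement(t0, ins_dur, ins_disp))
    t0 += ins_dur
    z_rel = -depth  # tip depth relative to skin after insertion

    # Adjustment phase: everyone spends a similar total time settling the
    # needle; skill decides how that time is chopped up.  The unskilled make
    # many brief corrective submovements separated by short arrests, the
    # skilled one or two deliberate ones — intermittency at matched
    # duration, which is the signature the smoothness metrics target.
    # Adjustment phase within a fixed time budget: few slow deliberate
    # corrections for the skilled, many quick jabs for the unskilled.
    n_corr = int(
        np.clip(round(1.0 + eff.submovement_rate * (1.0 - s) + rng.normal(0.0, 0.8)),
                1, 12)
    )
    budget = (
        eff.adjust_budget_s * (0.25 + 1.0 * (1.0 - s)) + rng.uniform(-0.5, 0.5)
    ) * pace
    budget = max(budget, 0.5 * pace)
    d_corr = (
        eff.correction_fast_s + (eff.correction_slow_s - eff.correction_fast_s) * s
    ) * pace
    move_total = min(n_corr * d_corr, 0.8 * budget)
    dur = move_total / n_corr
    hold = (budget - move_total) / n_corr
    for _ in range(n_corr):
        t0 += hold
        step = (4.0 + rng.uniform(0.0, 2.0)) * rng.uniform(0.7, 1.3)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        dz = rng.normal(0, 0.5)
        dz = float(np.clip(dz, -7.5 - z_rel, -1.0 - z_rel))  # stay 1–7.5 mm deep
        disp = np.array([step * np.cos(theta), step * np.sin(theta), dz])
        segments.append(Submovement(t0, dur, disp))
        t0 += dur
        z_rel += dz

    plan = SubmovementPlan(start=start, segments=segments, tail_hold_s=1.5 * pace)
    series = compose_trial(plan, spec.fs)
    # Electromagnetic-tracker noise amplitude varies trial to trial with
    # sensor pose and environment; draw each trial's peak level lognormally
    # around the cohort mean with the configured coefficient of variation.
    peak = spec.noise_peak_mean * _lognormal_unit_mean(rng, spec.noise_peak_cv)
    series = add_sensor_noise(series, peak, rng, bandwidth_hz=spec.noise_bandwidth_hz)
    flash, _ = simulate_flash(series, spec.skin_z, s, rng, eff)
    return series.replace(flash=flash)


def _lognormal_unit_mean(rng: np.random.Generator, cv: float) -> float:
    """Draw from a lognormal with mean 1 and the given coefficient of variation."""
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv**2)))
    return float(rng.lognormal(-(sigma**2) / 2.0, sigma))


def _grs_scores(
    skill: float, rng: np.random.Generator, noise_sd: float, rater_sd: float
) -> dict:
    """Expert Likert ratings: noisy discretised skill with a shared rater bias.

    Each participant is scored by a single expert, so a rater-severity
    offset (SD ``rater_sd`` on the latent [0, 1] scale) is common to all
    subscores and is the dominant reliability limit of the observer
    indicator; ``noise_sd`` is the per-subscore scatter on top of it.
    """
    bias = rng.normal(0.0, rater_sd)
    scores = {}
    for cat in GRS_CATEGORIES:
        latent = np.clip(skill + bias + rng.normal(0.0, noise_sd), 0.0, 1.0)
        scores[cat] = int(np.clip(round(1 + 6 * latent), 1, 7))
    return scores


def simulate_cohort(spec: CohortSpec, rng_seed) -> Cohort:
    """Generate a full cohort of trials plus participant-level indicators.

    Latent skill is drawn once per participant (truncated normal on [0, 1]);
    GRS subscores are discretised noisy skill, and years of experience are
    drawn with the configured correlation to skill.  Each trial perturbs the
    participant's skill with trial-level jitter feeding both kinematics and
    flashback.  Pure function of (spec, seed): same seed, identical cohort.
    """
    spec.validate()
    rng = _as_rng(rng_seed)
    eff = spec.effects
    records = []
    trials = []
    for p in range(spec.n_participants):
        pid = f"P{p + 1:03d}"
        skill = float(np.clip(rng.normal(spec.skill_mean, spec.skill_sd), 0.0, 1.0))
        grs = _grs_scores(skill, rng, eff.grs_noise_sd, eff.grs_rater_sd)
        rho = eff.exp_skill_corr
        z_skill = (skill - spec.skill_mean) / spec.skill_sd
        z_exp = rho * z_skill + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal()
        years = float(
            np.clip(eff.exp_mean_years + eff.exp_sd_years * z_exp, 0.0, eff.exp_max_years)
        )
        pace = _lognormal_unit_mean(rng, eff.pace_cv)
        records.append(
            {"participant_id": pid, "latent_skill": skill, "pace": pace,
             "years_experience": years,
             **{f"grs_{c}": v for c, v in grs.items()}}
        )
        for k in range(spec.trials_per_participant):
            tid = f"T{k + 1:02d}"
            fistula = (k % 4) + 1
            s_t = float(np.clip(rng.normal(skill, eff.trial_skill_sd), 0.0, 1.0))
            trial_pace = pace * _lognormal_unit_mean(rng, eff.trial_pace_cv)
            series = simulate_trial(s_t, spec, rng, fistula_id=fistula, pace=trial_pace)
            meta = TrialMeta(
                participant_id=pid,
                trial_id=tid,
                fistula_id=fistula,
                skin_z=spec.skin_z,
                fs=spec.fs,
                years_experience=years,
                grs=grs,
            )
            trials.append((series, meta))
    participants = pd.DataFrame.from_records(records)
    return Cohort(spec=spec, seed=rng_seed if isinstance(rng_seed, int) else -1,
                  trials=trials, participants=participants)
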