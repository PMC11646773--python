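"""Synthetic trials and outcome tables with the structure the analysis assumes.

Three generators, all seeded through one :class:`numpy.random.SeedSequence`
root with documented stream splitting (``spawn``), so identical seeds give
bit-identical output:

* :func:`simulate_sway_trial` — a quiet-stance force-plate record whose
  moment-balance COP follows a programmed Ornstein–Uhlenbeck (OU) path, the
  standard mean-reverting surrogate for postural sway, with optional
  sinusoidal mains hum added to the force channels. The ground-truth COP is
  returned for oracle tests.
* :func:`simulate_jump_trial` — a precision-jump trial whose toe marker lands
  at a programmed perpendicular offset from the target line while the landing
  plate shows a vertical-force step.
* :func:`simulate_cohort` — trial-level motor target errors drawn from a
  gamma distribution whose mean follows an inverse-link linear predictor with
  per-subject random intercepts and time slopes, plus normal cognitive and
  symptom outcomes with programmed main and time-by-skating interaction
  effects. The full ground truth is returned for recovery tests.

Cohort structure mirrors a three-arm pre/post design: an intervention group
with the condition of interest (PR), a waitlist control group with the
condition (PRCO), and an unaffected comparison group that receives the
intervention (ProKo).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import GenerationError, ParameterError
from .types import CopTrajectory, ForcePlateRecord, TrialRecord, TaskGeometry

__all__ = [
    "SwayParams",
    "CohortDesign",
    "NormalOutcomeSpec",
    "EffectSpec",
    "CohortTables",
    "simulate_sway_trial",
    "simulate_jump_trial",
    "simulate_cohort",
    "outcomes_table",
]

GROUPS = ("PR", "PRCO", "ProKo")  # (condition+intervention, condition-only, intervention-only)
TIMES = ("t1", "t2")
MOTOR_TASKS = ("balance", "one_leg_stand", "precision_jump")
COGNITIVE_VARIABLES = ("d2_completed", "d2_concentration", "stroop_time")
SYMPTOM_VARIABLES = ("attention_deficit", "hyperactivity")


@dataclass
class SwayParams:
    """Ornstein–Uhlenbeck sway surrogate plus plate synthesis parameters.

    ``mean_reversion`` (1/s) pulls the COP back to the stance center;
    ``diffusion`` (mm/sqrt(s)) drives the random excursions; ``hum_freq`` /
    ``hum_amplitude`` (Hz / N) add mains contamination to the force channels;
    ``body_weight`` (N) sets the vertical load (a ~40 kg child by default).
    """

    mean_reversion: float = 1.0
    diffusion: float = 15.0
    duration: float = 25.0
    rate: float = 1000.0
    hum_freq: float = 50.0
    hum_amplitude: float = 2.0
    body_weight: float = 390.0

    def __post_init__(self):
        if self.mean_reversion <= 0:
            raise ParameterError("mean_reversion must be positive")
        if self.diffusion < 0:
            raise ParameterError("diffusion must be non-negative")
        if self.duration <= 0:
            raise ParameterError("duration must be positive")
        if self.rate <= 2 * self.hum_freq:
            raise ParameterError("rate must exceed twice hum_freq")
        if self.hum_amplitude < 0:
            raise ParameterError("hum_amplitude must be non-negative")
        if self.body_weight <= 0:
            raise ParameterError("body_weight must be positive")


@dataclass
class CohortDesign:
    """Cohort sizes and session structure.

    ``n_per_group`` are the arm sizes in the order (PR, PRCO, ProKo); the
    study arms are (34, 14, 10). ``n_trials`` is the number of trials per
    motor task per session.
    """

    n_per_group: tuple = (34, 14, 10)
    n_trials: int = 6
    times: tuple = TIMES
    age_range: tuple = (8.0, 13.0)
    medication_rate: float = 0.5

    def __post_init__(self):
        if len(self.n_per_group) != 3 or any(n < 2 for n in self.n_per_group):
            raise ParameterError("n_per_group needs three groups with >= 2 subjects each")
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")
        if len(self.times) != 2:
            raise ParameterError("exactly two session labels are required")
        if not self.age_range[0] < self.age_range[1]:
            raise ParameterError("age_range must satisfy low < high")
        if not 0 <= self.medication_rate <= 1:
            raise ParameterError("medication_rate must be in [0, 1]")


@dataclass
class NormalOutcomeSpec:
    """Generating model for one normally distributed outcome.

    value = mean + adhd_shift*[condition] + time_shift*[post]
            + interaction_shift*[post & intervention]
            + subject effect + N(0, resid_sd)
    """

    mean: float
    adhd_shift: float = 0.0
    time_shift: float = 0.0
    interaction_shift: float = 0.0
    subject_sd: float = 1.0
    resid_sd: float = 1.0

    def __post_init__(self):
        if self.subject_sd < 0 or self.resid_sd < 0:
            raise ParameterError("standard deviations must be non-negative")


def _default_normal_outcomes() -> dict:
    # chosen once to emulate realistic score levels and pre/post change
    # magnitudes (~10-20% cognitive gains, ~15-20% symptom reductions)
    return {
        "d2_completed": NormalOutcomeSpec(425.0, -45.0, 40.0, 28.0, 55.0, 28.0),
        "d2_concentration": NormalOutcomeSpec(172.0, -22.0, 21.0, 9.0, 28.0, 14.0),
        "stroop_time": NormalOutcomeSpec(42.0, 6.0, -10.0, -0.5, 8.0, 4.0),
        "attention_deficit": NormalOutcomeSpec(0.9, 1.0, -0.29, -0.09, 0.40, 0.22),
        "hyperactivity": NormalOutcomeSpec(0.8, 0.7, -0.24, -0.05, 0.38, 0.22),
    }


@dataclass
class EffectSpec:
    """Ground-truth effect structure for the cohort generator.

    Motor target errors (mm) follow a gamma distribution with shape
    ``gamma_shape`` whose mean is ``baseline_error[task]`` multiplied by
    ``adhd_effect`` for affected subjects, ``time_effect`` at the post
    session, and additionally ``interaction_effect`` at post for subjects in
    the intervention arm. Subject random intercepts and time slopes act
    additively on the inverse-link linear predictor; their SDs are given as
    fractions of each task's baseline predictor 1/baseline_error (the three
    tasks have baselines differing by ~2x, so a single absolute SD would be
    meaningless across tasks). ``motor_latent_loading`` correlates a
    subject's intercepts across tasks; ``domain_latent_loading`` does the
    same for the normal outcomes within the cognitive and symptom domains.
    """

    baseline_error: dict = field(
        default_factory=lambda: {
            "balance": 30.0,
            "one_leg_stand": 25.0,
            "precision_jump": 50.0,
        }
    )
    adhd_effect: float = 1.25
    time_effect: float = 0.80
    interaction_effect: float = 0.91
    gamma_shape: float = 10.0
    re_sd_intercept: float = 0.12
    re_sd_slope: float = 0.03
    motor_latent_loading: float = 0.5
    normal_outcomes: dict = field(default_factory=_default_normal_outcomes)
    domain_latent_loading: float = 0.7

    def __post_init__(self):
        if any(v <= 0 for v in self.baseline_error.values()):
            raise ParameterError("baseline_error values must be positive")
        if self.adhd_effect < 0 or self.time_effect < 0 or self.interaction_effect < 0:
            raise ParameterError("effect factors must be non-negative")
        if self.gamma_shape <= 0:
            raise ParameterError("gamma_shape must be positive")
        if self.re_sd_intercept < 0 or self.re_sd_slope < 0:
            raise ParameterError("random-effect SDs must be non-negative")
        for lam in (self.motor_latent_loading, self.domain_latent_loading):
            if not 0 <= lam <= 1:
                raise ParameterError("latent loadings must be in [0, 1]")

    def null(self) -> "EffectSpec":
        """A copy with every systematic effect switched off (shifts 0,
        factors 1); group differences are then pure sampling noise."""
        outcomes = {
            k: NormalOutcomeSpec(v.mean, 0.0, 0.0, 0.0, v.subject_sd, v.resid_sd)
            for k, v in self.normal_outcomes.items()
        }
        return EffectSpec(
            baseline_error=dict(self.baseline_error),
            adhd_effect=1.0,
            time_effect=1.0,
            interaction_effect=1.0,
            gamma_shape=self.gamma_shape,
            re_sd_intercept=self.re_sd_intercept,
            re_sd_slope=self.re_sd_slope,
            motor_latent_loading=self.motor_latent_loading,
            normal_outcomes=outcomes,
            domain_latent_loading=self.domain_latent_loading,
        )


def simulate_sway_trial(
    params: SwayParams,
    center=(0.0, 0.0),
    seed: int = 0,
):
    """One quiet-stance trial: plate record + ground-truth COP trajectory.

    The COP follows an exactly discretized OU process around ``center`` (mm)
    in each planar coordinate, starting at the center. Force channels are
    synthesized as body weight on Fz (horizontal forces zero) with moments
    implied by the COP; sinusoidal hum at ``hum_freq`` is added to the force
    channels only, so the moment-balance COP of the emitted record equals the
    programmed path exactly when the hum amplitude is zero.
    """
    center = np.asarray(center, dtype=float).reshape(2)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = int(round(params.duration * params.rate))
    dt = 1.0 / params.rate
    theta = params.mean_reversion
    a = np.exp(-theta * dt)
    step_sd = params.diffusion * np.sqrt((1.0 - a * a) / (2.0 * theta))
    shocks = rng.standard_normal((n, 2)) * step_sd
    path = np.empty((n, 2))
    dev = np.zeros(2)
    for i in range(n):
        path[i] = center + dev
        dev = a * dev + shocks[i]
    cop_m = path / 1000.0
    bw = params.body_weight
    fz = np.full(n, bw)
    mx = cop_m[:, 1] * bw
    my = -cop_m[:, 0] * bw
    fx = np.zeros(n)
    fy = np.zeros(n)
    if params.hum_amplitude > 0:
        t = np.arange(n) * dt
        phases = rng.uniform(0, 2 * np.pi, size=3)
        hum = lambda ph: params.hum_amplitude * np.sin(
            2 * np.pi * params.hum_freq * t + ph
        )
        fx = fx + hum(phases[0])
        fy = fy + hum(phases[1])
        fz = fz + hum(phases[2])
    plate = ForcePlateRecord(
        fx=fx, fy=fy, fz=fz, mx=mx, my=my, mz=np.zeros(n), rate=params.rate
    )
    truth = CopTrajectory(
        xy=path, rate=params.rate, valid=np.ones(n, dtype=bool), provenance="single"
    )
    return plate, truth


def simulate_jump_trial(
    geometry: TaskGeometry,
    offset: float,
    landing_time: float,
    seed: int = 0,
    duration: float = 2.5,
    marker_rate: float = 200.0,
    force_rate: float = 1000.0,
    body_weight: float = 390.0,
    side: str = "both",
    subject: str = "synthetic",
) -> TrialRecord:
    """One precision-jump trial with a programmed landing offset (mm).

    The toe marker starts one jump distance behind the target line, flies a
    smooth arc, and from ``landing_time`` onward rests at the point offset by
    ``offset`` along the line's perpendicular. The landing plate's vertical
    force steps from zero to body weight at ``landing_time``.
    """
    if not 0 < landing_time < duration:
        raise ParameterError("landing_time must lie within the trial duration")
    a, b = geometry.jump_target_line
    direction = (b - a) / np.linalg.norm(b - a)
    normal = np.array([-direction[1], direction[0]])
    mid = 0.5 * (a + b)
    jump_dist = (
        geometry.jump_distance_double_mm
        if side == "both"
        else geometry.jump_distance_single_mm
    )
    start = mid - jump_dist * normal
    landing = mid + offset * normal
    n_m = int(round(duration * marker_rate))
    t_m = np.arange(n_m) / marker_rate
    takeoff = max(0.05, landing_time - 0.4)
    toe = np.empty((n_m, 3))
    for i, t in enumerate(t_m):
        if t < takeoff:
            toe[i, :2] = start
            toe[i, 2] = 0.0
        elif t < landing_time:
            tau = (t - takeoff) / (landing_time - takeoff)
            # quintic easing: zero velocity and acceleration at takeoff and
            # landing, so low-pass filtering does not smear the endpoints
            s = tau**3 * (6.0 * tau**2 - 15.0 * tau + 10.0)
            toe[i, :2] = start + s * (landing - start)
            toe[i, 2] = 4.0 * 150.0 * tau * (1.0 - tau)
        else:
            toe[i, :2] = landing
            toe[i, 2] = 0.0
    n_f = int(round(duration * force_rate))
    land_idx = int(round(landing_time * force_rate))
    fz = np.zeros(n_f)
    fz[land_idx:] = body_weight
    landing_m = landing / 1000.0
    mx = np.zeros(n_f)
    my = np.zeros(n_f)
    mx[land_idx:] = landing_m[1] * body_weight
    my[land_idx:] = -landing_m[0] * body_weight
    plate = ForcePlateRecord(
        fx=np.zeros(n_f),
        fy=np.zeros(n_f),
        fz=fz,
        mx=mx,
        my=my,
        mz=np.zeros(n_f),
        rate=force_rate,
        label="landing",
    )
    return TrialRecord(
        subject=subject,
        group="",
        time="t1",
        task="precision_jump",
        side=side,
        trial_index=0,
        markers={"toe": toe},
        marker_rate=marker_rate,
        plates=[plate],
        meta={
            "landing_time_s": landing_time,
            "programmed_offset_mm": float(offset),
            "seed": seed,
        },
    )


@dataclass
class CohortTables:
    """Output of :func:`simulate_cohort`: subject metadata, trial-level motor
    errors, cognitive/symptom scores, and the generating ground truth."""

    subjects: pd.DataFrame
    motor: pd.DataFrame
    scores: pd.DataFrame
    truth: dict


def _subject_table(design: CohortDesign, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    counter = 0
    for g, n in zip(GROUPS, design.n_per_group):
        adhd = 1 if g in ("PR", "PRCO") else 0
        skating = 1 if g in ("PR", "ProKo") else 0
        for _ in range(n):
            counter += 1
            rows.append(
                {
                    "subject": f"S{counter:03d}",
                    "group": g,
                    "ADHD": adhd,
                    "Skating": skating,
                    "Age": float(
                        np.round(rng.uniform(*design.age_range), 1)
                    ),
                    "Medication": int(rng.random() < design.medication_rate)
                    if adhd
                    else 0,
                }
            )
    return pd.DataFrame(rows)


def simulate_cohort(
    design: CohortDesign, effects: EffectSpec, seed: int = 0
) -> CohortTables:
    """Simulate a full pre/post cohort and return tables plus ground truth.

    Motor trial errors: for subject i, task k, session t the gamma mean is
    mu = 1/eta with eta = 1/mu_fixed + b0_ik + b1_ik * [t2], where mu_fixed
    multiplies the task baseline by the programmed effect factors and
    (b0, b1) are the subject's random intercept/slope on the linear-predictor
    scale. A non-positive eta raises :class:`GenerationError` with advice to
    shrink the random-effect SDs or effect factors.
    """
    root = np.random.SeedSequence(seed)
    ss_subj, ss_motor, ss_scores = root.spawn(3)
    rng_subj = np.random.default_rng(ss_subj)
    rng_motor = np.random.default_rng(ss_motor)
    rng_scores = np.random.default_rng(ss_scores)

    subjects = _subject_table(design, rng_subj)
    lam = effects.motor_latent_loading
    motor_latent = rng_motor.standard_normal(len(subjects))

    motor_rows = []
    re_rows = []
    cell_rows = []
    for i, subj in subjects.iterrows():
        g_m = motor_latent[i]
        for task in MOTOR_TASKS:
            base = effects.baseline_error[task]
            eta_base = 1.0 / base
            z0 = lam * g_m + np.sqrt(1 - lam**2) * rng_motor.standard_normal()
            b0 = effects.re_sd_intercept * eta_base * z0
            b1 = effects.re_sd_slope * eta_base * rng_motor.standard_normal()
            re_rows.append(
                {"subject": subj.subject, "task": task, "b0": b0, "b1": b1}
            )
            for time in design.times:
                post = int(time == design.times[1])
                mu_fixed = (
                    base
                    * (effects.adhd_effect if subj.ADHD else 1.0)
                    * (effects.time_effect if post else 1.0)
                    * (
                        effects.interaction_effect
                        if (post and subj.Skating)
                        else 1.0
                    )
                )
                eta = 1.0 / mu_fixed + b0 + b1 * post
                if eta <= 1e-12:
                    raise GenerationError(
                        f"non-positive gamma mean for subject {subj.subject}, "
                        f"task {task}, time {time}: linear predictor "
                        f"{eta:.3g} <= 0; reduce re_sd_intercept/re_sd_slope "
                        "or the effect factors"
                    )
                mu = 1.0 / eta
                values = rng_motor.gamma(
                    shape=effects.gamma_shape,
                    scale=mu / effects.gamma_shape,
                    size=design.n_trials,
                )
                cell_rows.append(
                    {
                        "subject": subj.subject,
                        "task": task,
                        "time": time,
                        "mu_mm": mu,
                        "eta": eta,
                    }
                )
                for trial, v in enumerate(values, start=1):
                    motor_rows.append(
                        {
                            "subject": subj.subject,
                            "group": subj.group,
                            "time": time,
                            "task": task,
                            "side": "",
                            "trial": trial,
                            "value_mm": float(v),
                            "n_valid": 0,
                        }
                    )
    motor = pd.DataFrame(motor_rows)

    lam_d = effects.domain_latent_loading
    cognitive_latent = rng_scores.standard_normal(len(subjects))
    symptom_latent = rng_scores.standard_normal(len(subjects))
    score_rows = []
    for i, subj in subjects.iterrows():
        for var, spec in effects.normal_outcomes.items():
            latent = cognitive_latent[i] if var in COGNITIVE_VARIABLES else symptom_latent[i]
            sign = -1.0 if var == "stroop_time" else 1.0
            subj_eff = spec.subject_sd * (
                sign * lam_d * latent
                + np.sqrt(1 - lam_d**2) * rng_scores.standard_normal()
            )
            for time in design.times:
                post = int(time == design.times[1])
                mean = (
                    spec.mean
                    + spec.adhd_shift * subj.ADHD
                    + spec.time_shift * post
                    + spec.interaction_shift * post * subj.Skating
                    + subj_eff
                )
                value = mean + spec.resid_sd * rng_scores.standard_normal()
                score_rows.append(
                    {
                        "subject": subj.subject,
                        "group": subj.group,
                        "time": time,
                        "variable": var,
                        "value": float(value),
                    }
                )
    scores = pd.DataFrame(score_rows)

    # expected %diff per variable on the mean scale (post vs pre), the
    # quantity the EMM-based post-hoc comparison recovers
    expected_pctdiff = {}
    for task in MOTOR_TASKS:
        expected_pctdiff[task] = {
            "control": 100.0 * (effects.time_effect - 1.0),
            "skating": 100.0
            * (effects.time_effect * effects.interaction_effect - 1.0),
        }
    for var, spec in effects.normal_outcomes.items():
        base_adhd = spec.mean + spec.adhd_shift
        expected_pctdiff[var] = {
            "control": 100.0 * spec.time_shift / base_adhd,
            "skating": 100.0 * (spec.time_shift + spec.interaction_shift) / base_adhd,
        }

    truth = {
        "seed": seed,
        "design": design,
        "effects": effects,
        "random_effects": pd.DataFrame(re_rows),
        "cell_means": pd.DataFrame(cell_rows),
        "expected_pctdiff": expected_pctdiff,
    }
    return CohortTables(subjects=subjects, motor=motor, scores=scores, truth=truth)


def outcomes_table(cohort: CohortTables) -> pd.DataFrame:
    """Merge motor trials and scores into the unified long outcome table.

    One row per subject x time x variable x trial for motor variables (the
    trial column indexes repeats) and one row per subject x time x variable
    for cognitive/symptom variables (trial = 0).
    """
    meta = cohort.subjects.set_index("subject")
    motor = cohort.motor.rename(columns={"task": "variable", "value_mm": "value"})[
        ["subject", "time", "variable", "trial", "value"]
    ]
    scores = cohort.scores[["subject", "time", "variable", "value"]].copy()
    scores["trial"] = 0
    long = pd.concat([motor, scores], ignore_index=True)
    for col in ("group", "ADHD", "Skating", "Age", "Medication"):
        long[col] = long["subject"].map(meta[col])
    order = [
        "subject",
        "group",
        "time",
        "ADHD",
        "Skating",
        "Age",
        "Medication",
        "variable",
        "trial",
        "value",
    ]
    return long[order].sort_values(
        ["variable", "subject", "time", "trial"], kind="mergesort"
    ).reset_index(drop=True)
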