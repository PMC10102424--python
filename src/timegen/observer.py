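"""Synthetic observers: generative same/different responses and heart-rate traces.

The generative model mirrors the analysis model: the probability of judging a
test duration "same" as the learned reference is a Gaussian profile on the
log10-duration axis,

    p_same(d) = baseline + amplitude * exp(-(log10 d - log10 PSE)^2 / (2 sigma^2)),

with generative width ``sigma = log10(1 + Wf)`` so that the Weber fraction of
a perfectly recovered fit equals the observer's true ``wf_true``.  Running
shifts the generative peak multiplicatively: while running the peak sits at
``pse_rest_s * running_gain``; a gain below 1 means a shorter test already
feels like the reference, i.e. duration is overestimated during running.
Sensory precision may likewise degrade during running through
``wf_running_gain`` (> 1 widens the profile).

Cohort-level distributions default to the published descriptive statistics of
the running/time-perception study this pipeline emulates (per-condition PSE
and Weber-fraction means and SDs for 2 modalities x 2 duration ranges x
2 motor conditions); they are the calibration constants of the simulator, not
quantities the pipeline re-estimates from real data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import DurationLadder, TrialSchedule, build_training_block
from .errors import InvalidInputError, InvalidSpecError

__all__ = [
    "ObserverParams",
    "CohortSpec",
    "HeartRateTrace",
    "RESPONSE_COLUMNS",
    "PSE_POPULATION",
    "WF_POPULATION",
    "p_same",
    "simulate_responses",
    "sample_cohort",
    "default_cohort_spec",
    "target_heart_rate",
    "simulate_hr_trace",
    "simulate_training",
]

#: Fixed column order of the trial-level response table.
RESPONSE_COLUMNS = [
    "participant_id",
    "modality",
    "range",
    "motor",
    "duration_s",
    "is_reference",
    "response",
]

# Published per-condition descriptive statistics used to calibrate the
# simulated cohort: (n, mean, sd) of the point of subjective equality in
# seconds, keyed by (modality, duration range, motor condition).
PSE_POPULATION = {
    ("visual", "milliseconds", "rest"): (29, 0.405, 0.044),
    ("visual", "milliseconds", "run"): (29, 0.366, 0.059),
    ("auditory", "milliseconds", "rest"): (23, 0.388, 0.047),
    ("auditory", "milliseconds", "run"): (23, 0.363, 0.056),
    ("visual", "seconds", "rest"): (29, 1.99, 0.176),
    ("visual", "seconds", "run"): (29, 1.90, 0.228),
    ("auditory", "seconds", "rest"): (23, 2.04, 0.279),
    ("auditory", "seconds", "run"): (23, 1.93, 0.231),
}

# Same for the Weber fraction (dimensionless).
WF_POPULATION = {
    ("visual", "milliseconds", "rest"): (29, 0.276, 0.065),
    ("visual", "milliseconds", "run"): (29, 0.32, 0.093),
    ("auditory", "milliseconds", "rest"): (23, 0.209, 0.047),
    ("auditory", "milliseconds", "run"): (23, 0.279, 0.076),
    ("visual", "seconds", "rest"): (29, 0.187, 0.065),
    ("visual", "seconds", "run"): (29, 0.222, 0.088),
    ("auditory", "seconds", "rest"): (23, 0.19, 0.05),
    ("auditory", "seconds", "run"): (23, 0.22, 0.085),
}

#: Reference duration (s) per duration range.
RANGE_REFERENCES = {"milliseconds": 0.4, "seconds": 2.0}

DEFAULT_AMPLITUDE = 0.85
DEFAULT_BASELINE = 0.05


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant in one condition."""

    pse_rest_s: float
    wf_true: float
    amplitude: float = DEFAULT_AMPLITUDE
    baseline: float = DEFAULT_BASELINE
    running_gain: float = 1.0
    wf_running_gain: float = 1.0
    participant_id: str = "obs"

    def __post_init__(self):
        if self.pse_rest_s <= 0:
            raise InvalidInputError(f"pse_rest_s must be positive, got {self.pse_rest_s}")
        if self.wf_true <= 0:
            raise InvalidInputError(f"wf_true must be positive, got {self.wf_true}")
        if self.running_gain <= 0 or self.wf_running_gain <= 0:
            raise InvalidInputError("gains must be positive")
        if not (0 <= self.baseline < self.baseline + self.amplitude <= 1):
            raise InvalidInputError(
                "require 0 <= baseline < baseline + amplitude <= 1, got "
                f"baseline={self.baseline}, amplitude={self.amplitude}"
            )

    def pse_s(self, motor: str) -> float:
        """Generative peak location in the given motor condition."""
        return self.pse_rest_s * (self.running_gain if motor == "run" else 1.0)

    def wf(self, motor: str) -> float:
        return self.wf_true * (self.wf_running_gain if motor == "run" else 1.0)

    def sigma_gen(self, motor: str = "rest") -> float:
        """Generative log10-width; the inverse of Wf = 10**sigma - 1."""
        return float(np.log10(1.0 + self.wf(motor)))


@dataclass(frozen=True)
class CohortSpec:
    """Population distributions a simulated cohort is drawn from.

    Means/SDs are given per motor condition; each participant receives a
    rest-condition PSE and Weber fraction from truncated normals (truncated
    at 0) plus multiplicative running gains whose population mean is the
    run/rest ratio of the condition means.
    """

    n_participants: int
    pse_rest_mean: float
    pse_rest_sd: float
    pse_run_mean: float
    pse_run_sd: float
    wf_rest_mean: float
    wf_rest_sd: float
    wf_run_mean: float
    wf_run_sd: float
    amplitude: float = DEFAULT_AMPLITUDE
    baseline: float = DEFAULT_BASELINE
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 1:
            raise InvalidSpecError("n_participants must be >= 1")
        for name in ("pse_rest_mean", "pse_run_mean", "wf_rest_mean", "wf_run_mean"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        for name in ("pse_rest_sd", "pse_run_sd", "wf_rest_sd", "wf_run_sd"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be non-negative")


def default_cohort_spec(
    modality: str,
    duration_range: str,
    n_participants: int | None = None,
    seed: int = 0,
    running_effect: bool = True,
) -> CohortSpec:
    """Cohort spec for one modality/range, calibrated to the published tables.

    With ``running_effect=False`` the run-condition distributions are set
    equal to the rest-condition ones (a null cohort: running gain exactly 1).
    """
    try:
        n_pub, pse_rest_m, pse_rest_sd = PSE_POPULATION[(modality, duration_range, "rest")]
        _, pse_run_m, pse_run_sd = PSE_POPULATION[(modality, duration_range, "run")]
        _, wf_rest_m, wf_rest_sd = WF_POPULATION[(modality, duration_range, "rest")]
        _, wf_run_m, wf_run_sd = WF_POPULATION[(modality, duration_range, "run")]
    except KeyError:
        raise InvalidSpecError(
            f"unknown condition {(modality, duration_range)!r}; expected modality in "
            "{'visual','auditory'} and range in {'milliseconds','seconds'}"
        ) from None
    if not running_effect:
        pse_run_m, pse_run_sd = pse_rest_m, pse_rest_sd
        wf_run_m, wf_run_sd = wf_rest_m, wf_rest_sd
    return CohortSpec(
        n_participants=n_participants if n_participants is not None else n_pub,
        pse_rest_mean=pse_rest_m,
        pse_rest_sd=pse_rest_sd,
        pse_run_mean=pse_run_m,
        pse_run_sd=pse_run_sd,
        wf_rest_mean=wf_rest_m,
        wf_rest_sd=wf_rest_sd,
        wf_run_mean=wf_run_m,
        wf_run_sd=wf_run_sd,
        seed=seed,
    )


def p_same(duration_s, params: ObserverParams, motor: str = "rest"):
    """Generative probability of a "same" response at a test duration.

    Vectorized over ``duration_s``.  The profile is a Gaussian in log10
    duration peaking at the motor-condition PSE.
    """
    d = np.asarray(duration_s, dtype=float)
    if np.any(d <= 0):
        raise InvalidInputError("durations must be positive")
    sigma = params.sigma_gen(motor)
    z = (np.log10(d) - np.log10(params.pse_s(motor))) / sigma
    p = params.baseline + params.amplitude * np.exp(-0.5 * z * z)
    return float(p) if np.isscalar(duration_s) else p


def simulate_responses(
    schedule: TrialSchedule,
    params: ObserverParams,
    motor: str = "rest",
    seed: int = 0,
    modality: str = "visual",
    duration_range: str = "milliseconds",
) -> pd.DataFrame:
    """Simulate one observer running one trial schedule.

    Each trial's response is an independent Bernoulli draw with success
    probability :func:`p_same` at that trial's duration.  Returns one row per
    trial with the fixed :data:`RESPONSE_COLUMNS` layout.
    """
    rng = np.random.default_rng(seed)
    durations = np.asarray(schedule.durations_s, dtype=float)
    probs = p_same(durations, params, motor)
    same = rng.random(len(durations)) < probs
    return pd.DataFrame(
        {
            "participant_id": params.participant_id,
            "modality": modality,
            "range": duration_range,
            "motor": motor,
            "duration_s": durations,
            "is_reference": np.asarray(schedule.is_reference, dtype=int),
            "response": np.where(same, "same", "different"),
        },
        columns=RESPONSE_COLUMNS,
    )


def _truncnorm_positive(mean, sd, size, rng):
    """Normal(mean, sd) truncated at zero; degenerates to the mean at sd=0."""
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _gain_sd(rest_mean, rest_sd, run_mean, run_sd):
    # Choose the gain spread so that Var(gain * pse_rest) approximately
    # reproduces the run-condition SD when gain and rest PSE are independent.
    g = run_mean / rest_mean
    excess = run_sd**2 - (g * rest_sd) ** 2
    return np.sqrt(max(excess, 0.0)) / rest_mean


def sample_cohort(spec: CohortSpec) -> list[ObserverParams]:
    """Draw a cohort of generative observers from a population spec.

    Rest-condition PSE and Weber fraction come from zero-truncated normals at
    the spec's rest means/SDs.  Each participant's running gains are drawn
    around the run/rest ratio of the condition means, with spread chosen so
    the implied run-condition SDs match the spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_participants
    pse = _truncnorm_positive(spec.pse_rest_mean, spec.pse_rest_sd, n, rng)
    wf = _truncnorm_positive(spec.wf_rest_mean, spec.wf_rest_sd, n, rng)
    g_pse = spec.pse_run_mean / spec.pse_rest_mean
    g_wf = spec.wf_run_mean / spec.wf_rest_mean
    gain_pse = _truncnorm_positive(
        g_pse, _gain_sd(spec.pse_rest_mean, spec.pse_rest_sd, spec.pse_run_mean, spec.pse_run_sd),
        n, rng,
    )
    gain_wf = _truncnorm_positive(
        g_wf, _gain_sd(spec.wf_rest_mean, spec.wf_rest_sd, spec.wf_run_mean, spec.wf_run_sd),
        n, rng,
    )
    return [
        ObserverParams(
            pse_rest_s=float(pse[i]),
            wf_true=float(wf[i]),
            amplitude=spec.amplitude,
            baseline=spec.baseline,
            running_gain=float(gain_pse[i]),
            wf_running_gain=float(gain_wf[i]),
            participant_id=f"P{i + 1:03d}",
        )
        for i in range(n)
    ]


def target_heart_rate(age_years: float, fraction: float = 0.8) -> float:
    """Exercise target heart rate: ``fraction * (208 - 0.7 * age)`` bpm.

    The age-predicted maximum uses the Tanaka formula; 0.8 is the protocol
    default (running at 80% of the age-predicted maximum).
    """
    if age_years <= 0:
        raise InvalidInputError(f"age must be positive, got {age_years}")
    if not 0 < fraction <= 1:
        raise InvalidInputError(f"fraction must lie in (0, 1], got {fraction}")
    return fraction * (208.0 - 0.7 * age_years)


@dataclass(frozen=True)
class HeartRateTrace:
    """A heart-rate time series: exponential ramp from rest to target, then plateau."""

    times_min: np.ndarray
    hr_bpm: np.ndarray
    rest_hr_bpm: float
    target_hr_bpm: float

    def run_mean(self, exclude_first_min: float = 3.0) -> float:
        """Mean running heart rate, excluding the initial ramp minutes."""
        mask = self.times_min >= exclude_first_min
        return float(np.mean(self.hr_bpm[mask]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times_min, "hr_bpm": self.hr_bpm})


def simulate_hr_trace(
    rest_hr: float,
    target: float,
    ramp_min: float = 3.0,
    total_min: float = 7.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    dt_s: float = 5.0,
) -> HeartRateTrace:
    """Simulate a heart-rate trace for one running block.

    Deterministic part: exponential approach from ``rest_hr`` to ``target``
    with time constant ``ramp_min / 3``, so the trace closes 95% of the gap by
    the end of the ramp and is flat thereafter.  I.i.d. Gaussian noise of SD
    ``noise_sd`` bpm is added on top.
    """
    if not (total_min > ramp_min > 0):
        raise InvalidInputError("require total_min > ramp_min > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, total_min + 1e-9, dt_s / 60.0)
    tau = ramp_min / 3.0
    hr = target - (target - rest_hr) * np.exp(-t / tau)
    hr = hr + rng.normal(0.0, noise_sd, size=t.shape)
    return HeartRateTrace(
        times_min=t, hr_bpm=hr, rest_hr_bpm=float(rest_hr), target_hr_bpm=float(target)
    )


def simulate_training(
    params: ObserverParams,
    ladder: DurationLadder,
    threshold: float = 0.85,
    max_blocks: int = 50,
    seed: int = 0,
) -> int:
    """Run the training phase block-by-block until the criterion passes.

    Training blocks present every ladder duration once; a response is correct
    when the observer says "same" exactly on the reference trial.  Returns the
    number of blocks needed (``max_blocks`` caps non-terminating observers).
    """
    from .design import training_criterion_met

    rng = np.random.default_rng(seed)
    for block in range(1, max_blocks + 1):
        sched = build_training_block(ladder, seed=int(rng.integers(2**31)))
        probs = p_same(np.asarray(sched.durations_s), params, "rest")
        said_same = rng.random(len(sched)) < probs
        correct = said_same == np.asarray(sched.is_reference)
        if training_criterion_met(correct.tolist(), threshold):
            return block
    return max_blocks
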