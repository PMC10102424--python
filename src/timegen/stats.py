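"""Effect sizes, power analysis, Bayes factors, and the mixed-ANOVA contract.

The running-induced shift of the point of subjective equality is summarized
per participant and condition by a normalized, scale-free effect

    effect = (PSE_rest - PSE_run) / (PSE_rest + PSE_run),

oriented so that a positive value means duration was overestimated while
running (the running PSE shrank).  Effects are tested against zero with the
default JZS Bayes factor (Cauchy prior on the standardized effect size,
scale sqrt(2)/2), and correlations carry a Bayes factor under a stretched
uniform prior on the population correlation.  Bayes factors are reported as
base-10 logarithms (LBF) with the conventional 0.47 / 1 / 2 evidence
thresholds.  Sample-size planning uses the noncentral-t power function of
the paired two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

from .errors import DegenerateDataError, InvalidDesignError, InvalidInputError, InvalidSpecError

__all__ = [
    "EffectRecord",
    "PowerSpec",
    "BayesResult",
    "normalized_effect",
    "hr_modulation",
    "paired_t_power",
    "required_n",
    "jzs_bf_onesample",
    "correlation_with_bf",
    "mixed_anova",
    "normality_check",
]

#: |LBF| thresholds for the substantial / strong / decisive evidence labels.
LBF_SUBSTANTIAL = 0.47
LBF_STRONG = 1.0
LBF_DECISIVE = 2.0

#: JZS default Cauchy prior scale on the standardized effect size.
DEFAULT_CAUCHY_SCALE = float(np.sqrt(2.0) / 2.0)


@dataclass(frozen=True)
class EffectRecord:
    """Per participant/condition normalized running effect and HR modulation."""

    participant_id: str
    modality: str
    duration_range: str
    normalized_effect: float
    hr_modulation_bpm: float


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of the paired-t sample-size computation."""

    effect_size_d: float
    alpha: float = 0.05
    power_target: float = 0.95
    tails: int = 2

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InvalidSpecError(f"alpha must lie in (0,1), got {self.alpha}")
        if not 0 < self.power_target < 1:
            raise InvalidSpecError(f"power_target must lie in (0,1), got {self.power_target}")
        if self.tails != 2:
            raise InvalidSpecError("only two-tailed tests are supported")


@dataclass(frozen=True)
class BayesResult:
    """A Bayes factor with its log10 and conventional evidence label."""

    bf10: float
    lbf: float
    evidence_label: str
    favors: str  # "H1" or "H0"

    @staticmethod
    def from_bf10(bf10: float) -> "BayesResult":
        lbf = float(np.log10(bf10))
        mag = abs(lbf)
        if mag > LBF_DECISIVE:
            label = "decisive"
        elif mag > LBF_STRONG:
            label = "strong"
        elif mag >= LBF_SUBSTANTIAL:
            label = "substantial"
        else:
            label = "weak"
        return BayesResult(
            bf10=float(bf10), lbf=lbf, evidence_label=label, favors="H1" if lbf >= 0 else "H0"
        )


def normalized_effect(pse_run: float, pse_rest: float) -> float:
    """Normalized running effect, positive when duration is overestimated.

    ``(pse_rest - pse_run) / (pse_rest + pse_run)``: antisymmetric under
    argument swap, invariant to common rescaling, and confined to (-1, 1)
    for positive PSEs.
    """
    if pse_run <= 0 or pse_rest <= 0:
        raise InvalidInputError("PSEs must be positive")
    return float((pse_rest - pse_run) / (pse_rest + pse_run))


def hr_modulation(run_hr_mean: float, rest_hr: float) -> float:
    """Run-minus-rest heart rate in bpm (run mean taken after the ramp)."""
    if run_hr_mean <= 0 or rest_hr <= 0:
        raise InvalidInputError("heart rates must be positive")
    return float(run_hr_mean - rest_hr)


def paired_t_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Achieved power of a two-tailed paired t-test.

    Under the alternative, the t statistic follows a noncentral t with
    ``df = n - 1`` and noncentrality ``d * sqrt(n)``; power is the
    probability it exceeds the two-tailed critical value in magnitude.
    """
    if n < 2:
        raise InvalidInputError(f"n must be >= 2, got {n}")
    if not 0 < alpha < 1:
        raise InvalidInputError(f"alpha must lie in (0,1), got {alpha}")
    df = n - 1
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = d * np.sqrt(n)
    upper = stats.nct.sf(t_crit, df, nc)
    lower = stats.nct.cdf(-t_crit, df, nc)
    # the far tail underflows to nan at extreme noncentrality; its mass is ~0
    if np.isnan(lower):
        lower = 0.0
    if np.isnan(upper):
        upper = 1.0 if nc > t_crit else 0.0
    return float(upper + lower)


def required_n(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest paired-t sample size achieving the target power.

    Increasing scan from n = 2; power is monotone in n so the first hit is
    the exact minimum.
    """
    if spec.effect_size_d <= 0:
        raise InvalidSpecError("effect size must be positive")
    for n in range(2, n_max + 1):
        if paired_t_power(spec.effect_size_d, n, spec.alpha) >= spec.power_target:
            return n
    raise InvalidSpecError(f"target power not reached by n = {n_max}")


def jzs_bf_onesample(values, cauchy_scale: float = DEFAULT_CAUCHY_SCALE) -> BayesResult:
    """Default (JZS) Bayes factor for a one-sample t-test against zero.

    The alternative places a Cauchy prior with the given scale on the
    standardized effect size delta; the Bayes factor is the ratio of the
    marginal likelihood of the observed t statistic under that prior
    (noncentral-t density integrated over delta) to its density under the
    point null.  Two-tailed by construction (the prior is symmetric).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2:
        raise InvalidInputError("need at least 2 values")
    if np.std(x, ddof=1) == 0:
        raise DegenerateDataError("zero-variance sample")
    t = float(stats.ttest_1samp(x, 0.0).statistic)
    df = n - 1
    sqrt_n = np.sqrt(n)

    def integrand(delta):
        return stats.nct.pdf(t, df, delta * sqrt_n) * stats.cauchy.pdf(delta, 0.0, cauchy_scale)

    num, _ = integrate.quad(integrand, -np.inf, np.inf, epsrel=1e-8)
    den = stats.t.pdf(t, df)
    return BayesResult.from_bf10(num / den)


def _pearson_density(r: float, rho: float, n: int) -> float:
    # Exact sampling density of the Pearson correlation of a bivariate
    # normal sample (hypergeometric form).
    return (
        (n - 2)
        * special.gamma(n - 1)
        * (1 - rho**2) ** ((n - 1) / 2)
        * (1 - r**2) ** ((n - 4) / 2)
        / (np.sqrt(2 * np.pi) * special.gamma(n - 0.5) * (1 - rho * r) ** (n - 1.5))
        * special.hyp2f1(0.5, 0.5, (2 * n - 1) / 2, (rho * r + 1) / 2)
    )


def correlation_with_bf(x, y, prior_width: float = 1.0) -> tuple[float, BayesResult]:
    """Pearson correlation with its two-tailed Bayes factor.

    The alternative places a stretched-beta prior of the given width on the
    population correlation (width 1 = uniform on (-1, 1)); the Bayes factor
    integrates the exact sampling density of r over that prior against the
    null density at rho = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InvalidInputError("need equal-length series with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateDataError("constant series")
    n = len(x)
    r = float(stats.pearsonr(x, y).statistic)
    # keep |r| strictly inside (-1, 1): the sampling density degenerates to
    # 0/0 at exact collinearity, where the BF is finite but enormous
    r_bf = float(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    a = 1.0 / prior_width

    def prior(rho):
        # Stretched beta(1/w, 1/w) on (-1, 1).
        return stats.beta.pdf((rho + 1) / 2, a, a) / 2

    num, _ = integrate.quad(lambda rho: _pearson_density(r_bf, rho, n) * prior(rho), -1, 1)
    den = _pearson_density(r_bf, 0.0, n)
    return r, BayesResult.from_bf10(num / den)


_ANOVA_TERMS = [
    ("Modality", "C(modality, Sum)[S.auditory]"),
    ("Range", "C(range, Sum)[S.milliseconds]"),
    ("Motor", "C(motor, Sum)[S.rest]"),
    ("Modality*Range", "C(modality, Sum)[S.auditory]:C(range, Sum)[S.milliseconds]"),
    ("Modality*Motor", "C(modality, Sum)[S.auditory]:C(motor, Sum)[S.rest]"),
    ("Range*Motor", "C(range, Sum)[S.milliseconds]:C(motor, Sum)[S.rest]"),
    (
        "Modality*Range*Motor",
        "C(modality, Sum)[S.auditory]:C(range, Sum)[S.milliseconds]:C(motor, Sum)[S.rest]",
    ),
]


def mixed_anova(table: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Linear mixed-model ANOVA on a long-format PSE or Weber-fraction table.

    Fixed effects: modality, duration range, motor condition and all
    interactions (sum coding); random intercept per participant; unbalanced
    designs (participants who did only one modality) are handled naturally.
    Estimation delegates to statsmodels' MixedLM; each 1-df term is tested
    with a Wald statistic reported as F with its p-value.  The contract is
    the direction and significance pattern of the terms, not a particular
    denominator-degrees-of-freedom convention.
    """
    import statsmodels.formula.api as smf

    required = {"participant_id", "modality", "range", "motor", dv}
    missing = required - set(table.columns)
    if missing:
        raise InvalidDesignError(f"missing columns: {sorted(missing)}")
    for factor in ("modality", "range", "motor"):
        if table[factor].nunique() < 2:
            raise InvalidDesignError(f"factor {factor!r} has a single level")
    # Wald z-statistics are invariant to affine rescaling of the dv;
    # standardizing stabilizes the profile-likelihood optimization when one
    # factor (duration range) dominates the raw scale.
    data = table.copy()
    data["_dv"] = (data[dv] - data[dv].mean()) / data[dv].std(ddof=1)
    model = smf.mixedlm(
        "_dv ~ C(modality, Sum) * C(range, Sum) * C(motor, Sum)",
        data=data,
        groups=data["participant_id"],
    )
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with np.errstate(all="ignore"), warnings.catch_warnings():
        # A random-intercept variance estimated at zero is a legitimate
        # boundary solution, not a failure.
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.filterwarnings("ignore", message="Random effects covariance is singular")
        res = None
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if res is None:
            raise InvalidDesignError("mixed-model estimation failed to converge")
    rows = []
    resid_df = res.nobs - len(res.fe_params)
    for term, coef in _ANOVA_TERMS:
        z = res.fe_params[coef] / res.bse_fe[coef]
        f = float(z**2)
        p = float(stats.f.sf(f, 1, resid_df))
        rows.append({"term": term, "F": f, "df_num": 1, "df_den": int(resid_df), "p": p})
    return pd.DataFrame(rows).set_index("term")


def normality_check(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test; returns (statistic, p-value).

    Used as a pipeline gate with a logged warning, never a hard stop.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise InvalidInputError("need at least 3 values")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant input")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)
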