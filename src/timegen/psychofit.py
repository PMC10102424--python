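"""Gaussian generalization-profile fitting: PSE and Weber fraction estimation.

The proportion of "same" responses as a function of test duration forms a
generalization profile that peaks near the learned reference.  We fit

    p(d) = baseline + amplitude * exp(-(log10 d - mu)^2 / (2 sigma^2))

by bounded, count-weighted least squares.  The fitted peak location is the
point of subjective equality, ``PSE = 10**mu`` seconds, and the fitted
log10-width maps to the Weber fraction through ``Wf = 10**sigma - 1``:
a profile whose SD spans a factor ``10**sigma`` in duration corresponds to a
relative just-noticeable difference of ``10**sigma - 1``.

Fitting is deterministic: a fixed multi-start grid seeds a bounded
trust-region optimizer and the lowest final loss wins; no RNG is involved.
Per-participant fits with R^2 at or below 0.7 are flagged for exclusion from
downstream statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    DegenerateDataError,
    FitFailureError,
    IncompleteCurveError,
    InvalidInputError,
)

__all__ = [
    "GeneralizationCurve",
    "GaussianFit",
    "FitOptions",
    "R2_EXCLUSION_THRESHOLD",
    "tabulate",
    "fit_gaussian",
    "weber_fraction",
    "r_squared",
]

#: Fits with R^2 at or below this are excluded from downstream statistics.
R2_EXCLUSION_THRESHOLD = 0.7


@dataclass(frozen=True)
class GeneralizationCurve:
    """Per-duration counts of "same" responses — the fit input."""

    durations_s: np.ndarray
    n_same: np.ndarray
    n_total: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.durations_s, dtype=float)
        ns = np.asarray(self.n_same, dtype=int)
        nt = np.asarray(self.n_total, dtype=int)
        if not (len(d) == len(ns) == len(nt)):
            raise InvalidInputError("curve arrays must have equal length")
        if np.any(np.diff(d) <= 0):
            raise InvalidInputError("durations must be strictly increasing")
        if np.any(ns < 0) or np.any(ns > nt):
            raise InvalidInputError("require 0 <= n_same <= n_total per duration")
        object.__setattr__(self, "durations_s", d)
        object.__setattr__(self, "n_same", ns)
        object.__setattr__(self, "n_total", nt)

    @property
    def proportions(self) -> np.ndarray:
        return self.n_same / self.n_total

    def __add__(self, other: "GeneralizationCurve") -> "GeneralizationCurve":
        if not np.allclose(self.durations_s, other.durations_s):
            raise InvalidInputError("cannot pool curves over different ladders")
        return GeneralizationCurve(
            self.durations_s, self.n_same + other.n_same, self.n_total + other.n_total
        )


@dataclass(frozen=True)
class GaussianFit:
    """A fitted generalization profile; carrier of the PSE and Weber fraction."""

    mu_log10: float
    sigma_log10: float
    amplitude: float
    baseline: float
    r_squared: float
    loss: float

    @property
    def pse_s(self) -> float:
        """Point of subjective equality in seconds (the fitted peak)."""
        return float(10.0**self.mu_log10)

    @property
    def wf(self) -> float:
        """Weber fraction, ``10**sigma - 1``."""
        return weber_fraction(self.sigma_log10)

    @property
    def excluded(self) -> bool:
        return not self.r_squared > R2_EXCLUSION_THRESHOLD

    def predict(self, durations_s) -> np.ndarray:
        x = np.log10(np.asarray(durations_s, dtype=float))
        z = (x - self.mu_log10) / self.sigma_log10
        return self.baseline + self.amplitude * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_gaussian`.

    weighted
        Weight squared residuals by trial counts (the reference duration has
        three times the trials of the other rungs).
    baseline_free
        Fit the floor parameter; if False the baseline is pinned at 0.
    sigma_bounds
        Allowed range of the log10-width.
    """

    weighted: bool = True
    baseline_free: bool = True
    sigma_bounds: tuple[float, float] = (0.01, 1.0)


def tabulate(dataset: pd.DataFrame, ladder=None, **selector) -> GeneralizationCurve:
    """Aggregate trial-level responses into a generalization curve.

    ``selector`` keyword arguments filter rows by equality on columns (e.g.
    ``participant_id="P001", motor="run"``).  Reference and non-reference
    trials at the same duration pool together.  If ``ladder`` is given the
    curve must cover every ladder duration, otherwise an
    :class:`IncompleteCurveError` lists the absent levels.
    """
    df = dataset
    for col, val in selector.items():
        df = df[df[col] == val]
    if len(df) == 0:
        raise IncompleteCurveError(ladder.durations_s if ladder is not None else [])
    grouped = df.groupby("duration_s", sort=True)["response"].agg(
        n_same=lambda s: int((s == "same").sum()), n_total="size"
    )
    if ladder is not None:
        missing = [d for d in ladder.durations_s if not np.any(np.isclose(grouped.index, d))]
        if missing:
            raise IncompleteCurveError(missing)
    return GeneralizationCurve(
        durations_s=grouped.index.to_numpy(),
        n_same=grouped["n_same"].to_numpy(),
        n_total=grouped["n_total"].to_numpy(),
    )


def weber_fraction(sigma_log10: float) -> float:
    """Map a log10 Gaussian width to a Weber fraction: ``10**sigma - 1``."""
    if sigma_log10 <= 0:
        raise InvalidInputError(f"sigma_log10 must be positive, got {sigma_log10}")
    return float(10.0**sigma_log10 - 1.0)


def _loss(theta, x, p, w):
    mu, sigma, amp, base = theta
    z = (x - mu) / sigma
    resid = base + amp * np.exp(-0.5 * z * z) - p
    return float(np.sum(w * resid * resid))


#: Number of best-scoring grid starts handed to the bounded refiner.
N_REFINED_STARTS = 6


def _starts(x, p, options):
    """Deterministic multi-start grid covering peak location and width."""
    amp_data = float(np.clip(p.max() - p.min(), 0.05, 1.0))
    base_data = float(np.clip(p.min(), 0.0, 0.95)) if options.baseline_free else 0.0
    lo, hi = options.sigma_bounds
    sigmas = [s for s in (0.05, 0.1, 0.2, 0.4) if lo <= s <= hi] or [np.sqrt(lo * hi)]
    amp_base = [(amp_data, base_data)]
    if options.baseline_free:
        amp_base.append((min(1.0, amp_data + base_data), 0.0))
    starts = []
    for mu0 in x:
        for s0 in sigmas:
            for a0, b0 in amp_base:
                starts.append(np.array([mu0, s0, a0, b0]))
    return starts


def fit_gaussian(curve: GeneralizationCurve, options: FitOptions = FitOptions()) -> GaussianFit:
    """Fit the 4-parameter Gaussian profile to a generalization curve.

    Count-weighted least squares on the log10-duration axis with box bounds
    (peak within the ladder span plus one step; width within
    ``options.sigma_bounds``; amplitude and baseline within the unit
    interval).  Every start on a fixed coarse grid is refined with a bounded
    trust-region solver; the best final loss wins, making the fit
    deterministic for given inputs and options.
    """
    if len(curve.durations_s) < 4:
        raise InvalidInputError("need >= 4 distinct durations to fit 4 parameters")
    x = np.log10(curve.durations_s)
    p = curve.proportions
    w = curve.n_total.astype(float) if options.weighted else np.ones_like(p)
    sw = np.sqrt(w)
    step = np.median(np.diff(x))
    lo_s, hi_s = options.sigma_bounds
    base_hi = 1.0 if options.baseline_free else 1e-12
    lower = np.array([x[0] - step, lo_s, 1e-6, 0.0])
    upper = np.array([x[-1] + step, hi_s, 1.0, base_hi])

    def residuals(theta):
        mu, sigma, amp, base = theta
        z = (x - mu) / sigma
        return sw * (base + amp * np.exp(-0.5 * z * z) - p)

    # Score every grid start cheaply, refine only the most promising ones;
    # trust-region refinement never increases the loss of its start, so the
    # returned fit is at least as good as the best grid start.
    starts = [np.clip(s, lower, upper) for s in _starts(x, p, options)]
    scores = np.array([_loss(s, x, p, w) for s in starts])
    order = np.argsort(scores, kind="stable")[:N_REFINED_STARTS]
    best = None
    for idx in order:
        try:
            res = least_squares(
                residuals,
                starts[idx],
                bounds=(lower, upper),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        if res.status == -1 or not np.all(np.isfinite(res.x)):
            continue
        # status 0 (evaluation budget reached) still carries the best point
        # found from this start; only outright failures are discarded
        loss = _loss(res.x, x, p, w)
        if best is None or loss < best[0]:
            best = (loss, res.x)
    if best is None:
        raise FitFailureError("Gaussian fit failed to converge from every start")
    loss, (mu, sigma, amp, base) = best
    fit = GaussianFit(
        mu_log10=float(mu),
        sigma_log10=float(sigma),
        amplitude=float(amp),
        baseline=float(base),
        r_squared=np.nan,
        loss=loss,
    )
    r2 = r_squared(curve, fit)
    return GaussianFit(
        mu_log10=fit.mu_log10,
        sigma_log10=fit.sigma_log10,
        amplitude=fit.amplitude,
        baseline=fit.baseline,
        r_squared=r2,
        loss=loss,
    )


def r_squared(curve: GeneralizationCurve, fit: GaussianFit) -> float:
    """Coefficient of determination of a fit over the curve's proportions.

    Unweighted, with total sum of squares about the mean proportion.
    """
    p = curve.proportions
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("R^2 undefined: zero variance in proportions")
    resid = p - fit.predict(curve.durations_s)
    return float(1.0 - np.sum(resid**2) / ss_tot)
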