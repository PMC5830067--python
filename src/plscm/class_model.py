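"""Class modeling of the calculated PLS response.

The class-modeling step turns the PLS regression into a pair of hypothesis
tests.  For each class the responses calculated by the model (values near 0
for class 0 and near 1 for class 1) are fitted with a normal density,
justified by a normality test.  With the null hypothesis "the sample belongs
to class 0", a threshold ``t`` on the response axis yields

    alpha(t) = P( N(mu0, sigma0) on the class-1 side of t )   (type I error)
    beta(t)  = P( N(mu1, sigma1) on the class-0 side of t )   (type II error)

Sweeping ``t`` traces the risk curve beta versus alpha; the equal-error
threshold where alpha = beta has the closed form

    t* = (mu0 * sigma1 + mu1 * sigma0) / (sigma0 + sigma1)

at which both standardized distances equal |mu1 - mu0| / (sigma0 + sigma1)
and sensitivity (1 - alpha) x 100 equals specificity (1 - beta) x 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ClassCoding
from .exceptions import DegenerateDensityError, InsufficientDataError

__all__ = [
    "ClassDensityModel",
    "RiskCurve",
    "OperatingPoint",
    "NormalityWarning",
    "fit_class_densities",
    "risk_curve",
    "equal_error_point",
    "signed_sensitivity",
    "assign_samples",
]


class NormalityWarning(UserWarning):
    """A class's calculated responses failed the normality screen."""


@dataclass(frozen=True)
class ClassDensityModel:
    """Per-class normal parameters of the calculated response.

    ``sigma*`` use the n-1 denominator.  ``normality_p*`` are Shapiro-Wilk
    p-values (NaN when a class is too small to test); values at or below the
    chosen level flag the normal fit as questionable without blocking it.
    """

    mu0: float
    sigma0: float
    mu1: float
    sigma1: float
    normality_p0: float = float("nan")
    normality_p1: float = float("nan")
    normality_ok: bool = True

    def __post_init__(self) -> None:
        if not (self.sigma0 > 0 and self.sigma1 > 0):
            raise DegenerateDensityError("class standard deviations must be positive")

    @property
    def orientation(self) -> int:
        """+1 if class 1 sits above class 0 on the response axis, else -1."""
        return 1 if self.mu1 >= self.mu0 else -1


@dataclass(frozen=True)
class RiskCurve:
    """Threshold sweep of (alpha, beta) over the response axis."""

    thresholds: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def equal_error_index(self) -> int:
        return int(np.argmin(np.abs(self.alpha - self.beta)))


@dataclass(frozen=True)
class OperatingPoint:
    """One threshold with its error probabilities and percent rates."""

    threshold: float
    alpha: float
    beta: float

    @property
    def sensitivity(self) -> float:
        return (1.0 - self.alpha) * 100.0

    @property
    def specificity(self) -> float:
        return (1.0 - self.beta) * 100.0

    @property
    def sensitivity_pct(self) -> int:
        """Integer-rounded sensitivity, as quoted in reports."""
        return int(round(self.sensitivity))

    @property
    def specificity_pct(self) -> int:
        return int(round(self.specificity))


def fit_class_densities(
    y_hat: np.ndarray,
    labels: np.ndarray,
    normality_alpha: float = 0.10,
) -> ClassDensityModel:
    """Fit a normal density per class to the calculated responses.

    Requires at least three samples per class.  Shapiro-Wilk p-values are
    attached; a p-value at or below ``normality_alpha`` raises a
    :class:`NormalityWarning` (the model is still returned — the normal fit
    is the method's stated assumption, and the warning is the evidence
    trail).
    """
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if y_hat.shape != labels.shape:
        raise ValueError("y_hat and labels must have equal length")
    g0 = y_hat[labels == 0]
    g1 = y_hat[labels == 1]
    if len(g0) < 3 or len(g1) < 3:
        raise InsufficientDataError("need >= 3 samples per class")

    mu0, mu1 = float(g0.mean()), float(g1.mean())
    s0 = float(g0.std(ddof=1))
    s1 = float(g1.std(ddof=1))
    if s0 <= 0 or s1 <= 0:
        raise DegenerateDensityError(
            "a class has zero variance in its calculated responses"
        )

    p0 = float(stats.shapiro(g0).pvalue)
    p1 = float(stats.shapiro(g1).pvalue)
    ok = p0 > normality_alpha and p1 > normality_alpha
    if not ok:
        warnings.warn(
            f"normality test p-values ({p0:.3g}, {p1:.3g}) not above "
            f"{normality_alpha}; normal class densities may be inadequate",
            NormalityWarning,
            stacklevel=2,
        )
    return ClassDensityModel(
        mu0=mu0, sigma0=s0, mu1=mu1, sigma1=s1,
        normality_p0=p0, normality_p1=p1, normality_ok=ok,
    )


def _error_probs(model: ClassDensityModel, t: np.ndarray | float):
    """alpha(t), beta(t) with orientation handled (class 1 above or below)."""
    t = np.asarray(t, dtype=float)
    if model.orientation > 0:
        alpha = stats.norm.sf(t, loc=model.mu0, scale=model.sigma0)
        beta = stats.norm.cdf(t, loc=model.mu1, scale=model.sigma1)
    else:
        alpha = stats.norm.cdf(t, loc=model.mu0, scale=model.sigma0)
        beta = stats.norm.sf(t, loc=model.mu1, scale=model.sigma1)
    return alpha, beta


def risk_curve(model: ClassDensityModel, grid_size: int = 2001) -> RiskCurve:
    """Sweep thresholds over [min(mu) - 4 max(sigma), max(mu) + 4 max(sigma)]."""
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if model.mu0 == model.mu1:
        raise DegenerateDensityError("class means coincide; no risk curve")
    smax = max(model.sigma0, model.sigma1)
    lo = min(model.mu0, model.mu1) - 4.0 * smax
    hi = max(model.mu0, model.mu1) + 4.0 * smax
    t = np.linspace(lo, hi, int(grid_size))
    alpha, beta = _error_probs(model, t)
    return RiskCurve(thresholds=t, alpha=alpha, beta=beta)


def equal_error_point(model: ClassDensityModel) -> OperatingPoint:
    """Closed-form threshold where the type I and type II risks coincide."""
    if model.mu0 == model.mu1:
        raise DegenerateDensityError("class means coincide; equal-error undefined")
    t_star = (model.mu0 * model.sigma1 + model.mu1 * model.sigma0) / (
        model.sigma0 + model.sigma1
    )
    z = abs(model.mu1 - model.mu0) / (model.sigma0 + model.sigma1)
    err = float(stats.norm.sf(z))
    return OperatingPoint(threshold=float(t_star), alpha=err, beta=err)


def signed_sensitivity(model: ClassDensityModel) -> float:
    """Equal-error sensitivity in percent, with the class orientation signed.

    ``equal_error_point`` is orientation-aware and therefore never reports
    below 50% — it flips sides when the class-1 mean falls below the
    class-0 mean.  For simulation summaries that must distinguish "no
    discrimination" (about 50%) from "anti-discrimination" (below 50%),
    this helper keeps the sign of the standardized class separation:

        Phi( (mu1 - mu0) / (sigma0 + sigma1) ) x 100

    which equals the equal-error sensitivity when class 1 sits above
    class 0 and its mirror image otherwise.
    """
    z = (model.mu1 - model.mu0) / (model.sigma0 + model.sigma1)
    return float(stats.norm.cdf(z) * 100.0)


def assign_samples(
    y_hat: np.ndarray,
    point: OperatingPoint,
    model: ClassDensityModel,
    labels: np.ndarray | None = None,
    coding: ClassCoding | None = None,
):
    """Assign each sample by thresholding its calculated response.

    With the usual orientation (mu0 < mu1), responses below the threshold go
    to class 0 and responses at or above it to class 1 (ties to class 1 by
    convention); the rule mirrors when class 1 lies below class 0.

    Returns
    -------
    assignments : (n,) int array of 0/1 codes
    confusion : 2x2 int array ``confusion[true, assigned]`` when true
        labels are given, else None.
    """
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if model.orientation > 0:
        assigned = (y_hat >= point.threshold).astype(int)
    else:
        assigned = (y_hat <= point.threshold).astype(int)
    confusion = None
    if labels is not None:
        labels = np.asarray(labels, dtype=int).ravel()
        confusion = np.zeros((2, 2), dtype=int)
        for true, pred in zip(labels, assigned):
            confusion[true, pred] += 1
    if coding is not None:
        named = [coding.label(int(a)) for a in assigned]
        return assigned, confusion, named
    return assigned, confusion
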