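"""Univariate screens and the CD4-slope case/control rule.

Two-group comparisons use the Mann-Whitney U test with two-sided p-values
and significance declared at p < 0.05 per variable, with *no* multiple-
testing correction: the screen is run variable by variable across the whole
panel, exactly as practised in the source analyses, and the absence of
correction is deliberately preserved (and prominently noted here) rather
than silently "fixed".

The screen complements the multivariate model in two ways: it partitions
variables by (selected by VIP) x (univariately significant) — unselected
but significant variables are the ones the unnormalized PLS misses through
a pure numerical (scale) effect — and it checks that variables carrying
more weight in the model tend to have smaller univariate p-values (a
negative rank correlation between |coefficient| and p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import CD4Trajectory, PhenotypeMatrix
from .exceptions import InsufficientDataError
from .pls import PLSModel

__all__ = [
    "MannWhitneyResult",
    "SignificancePartition",
    "SlopeClassification",
    "mann_whitney",
    "screen_variables",
    "loading_pvalue_association",
    "partition_by_selection",
    "classify_cd4_slope",
]

# combined sample size at or below which the exact null distribution is used
# (only meaningful without ties; scipy enumerates it)
_EXACT_N_MAX = 12


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"


@dataclass(frozen=True)
class SignificancePartition:
    """Cross-tabulation of VIP selection against univariate significance."""

    n_selected_significant: int
    n_selected_nonsignificant: int
    n_unselected_significant: int
    n_unselected_nonsignificant: int

    @property
    def total(self) -> int:
        return (
            self.n_selected_significant
            + self.n_selected_nonsignificant
            + self.n_unselected_significant
            + self.n_unselected_nonsignificant
        )


@dataclass(frozen=True)
class SlopeClassification:
    """CD4 slope with its test against zero and the case/control verdict.

    ``category`` is "case" iff the slope is significantly negative; a flat
    or significantly *positive* slope both mean "control" — the rule is
    one-sided on the sign of a two-sided test.
    """

    subject_id: str
    slope: float  # cells/uL per year
    slope_p: float
    category: str  # "case" | "control"


def mann_whitney(x0, x1) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Uses the exact null distribution when the combined sample size is at
    most 12 and there are no ties; otherwise the midrank normal
    approximation with tie correction and continuity correction.  ``U`` is
    reported for the first sample.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    x1 = np.asarray(x1, dtype=float).ravel()
    if len(x0) == 0 or len(x1) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x0, x1])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= _EXACT_N_MAX and not has_ties:
        res = stats.mannwhitneyu(x0, x1, alternative="two-sided", method="exact")
        return MannWhitneyResult(float(res.statistic), float(res.pvalue), "exact")
    res = stats.mannwhitneyu(
        x0, x1, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), "normal_approx")


def screen_variables(
    matrix: PhenotypeMatrix, alpha: float = 0.05
) -> list[MannWhitneyResult]:
    """One Mann-Whitney test per variable, class 0 versus class 1.

    No multiple-testing correction is applied; significance is the raw
    two-sided p below ``alpha`` and is left to the caller to threshold.
    """
    mask1 = matrix.class_labels == 1
    results = []
    for j in range(matrix.n_variables):
        col = matrix.values[:, j]
        results.append(mann_whitney(col[~mask1], col[mask1]))
    return results


def significant_indices(
    results: list[MannWhitneyResult], alpha: float = 0.05
) -> list[int]:
    return [j for j, r in enumerate(results) if r.p_two_sided < alpha]


def loading_pvalue_association(
    stage2_model: PLSModel,
    screen: list[MannWhitneyResult],
    weight_kind: str = "coefficients",
) -> tuple[float, float]:
    """Spearman rank correlation between variable weight magnitude and p-value.

    ``screen`` must cover exactly the stage-2 (selected) variables, in the
    model's column order.  ``weight_kind`` picks which per-variable summary
    plays the role of the "loading": the composite regression coefficients
    (default), the first-component weights, or the first-component
    X-loadings.  On discriminative data the correlation is expected to be
    negative: heavier variables earn smaller p-values.
    """
    if weight_kind == "coefficients":
        w = stage2_model.coefficients
    elif weight_kind == "weights":
        w = stage2_model.weights[:, 0]
    elif weight_kind == "x_loadings":
        w = stage2_model.x_loadings[:, 0]
    else:
        raise ValueError(f"unknown weight_kind {weight_kind!r}")
    if len(screen) != len(w):
        raise ValueError(
            f"screen covers {len(screen)} variables, model has {len(w)}"
        )
    if len(w) < 4:
        raise InsufficientDataError("need >= 4 variables for a rank correlation")
    pvals = np.array([r.p_two_sided for r in screen])
    if np.all(pvals == pvals[0]) or np.all(np.abs(w) == np.abs(w[0])):
        raise InsufficientDataError("constant ranks; correlation undefined")
    rho, p = stats.spearmanr(np.abs(w), pvals)
    return float(rho), float(p)


def partition_by_selection(
    selected: list[int],
    screen: list[MannWhitneyResult],
    alpha: float = 0.05,
) -> SignificancePartition:
    """Cross-tabulate selection by significance over all screened variables."""
    sel = set(selected)
    sig = set(significant_indices(screen, alpha))
    all_idx = set(range(len(screen)))
    return SignificancePartition(
        n_selected_significant=len(sel & sig),
        n_selected_nonsignificant=len(sel - sig),
        n_unselected_significant=len(sig - sel),
        n_unselected_nonsignificant=len(all_idx - sel - sig),
    )


def classify_cd4_slope(traj: CD4Trajectory, alpha: float = 0.05) -> SlopeClassification:
    """OLS slope of CD4 count on time with a t-test against zero.

    "Case" means immunological progression: a statistically significant
    *negative* slope.  Everything else — flat or significantly increasing —
    is "control".
    """
    if np.ptp(traj.times) == 0:
        raise ValueError(f"subject '{traj.subject_id}': zero time variance")
    fit = stats.linregress(traj.times, traj.counts)
    slope = float(fit.slope)
    p = float(fit.pvalue)
    category = "case" if (p < alpha and slope < 0) else "control"
    return SlopeClassification(
        subject_id=traj.subject_id, slope=slope, slope_p=p, category=category
    )
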