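"""Variable influence on projection (VIP) and the two-stage fit-select-refit.

VIP summarizes the importance of each predictor for the model, weighting the
squared (unit-norm) PLS weights by how much response variance each latent
variable explains:

    VIP_j = sqrt( p * sum_a SSY_a * w_ja^2 / sum_a SSY_a )

where ``SSY_a`` is the y-block sum of squares captured by component ``a``
and ``p`` the variable count.  The normalization makes the mean squared VIP
exactly 1, so the conventional cut "VIP greater than 1" keeps the variables
that are more influential than average.  Selection here is strict (> 1, not
>=), and the workflow mirrors the class-modeling practice: fit on the full
matrix, keep the VIP > threshold columns, refit on the reduced matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import SelectionFailureError, UndefinedVIPError
from .pls import PLSModel, fit_pls, predict

__all__ = [
    "VIPScores",
    "SelectionResult",
    "compute_vip",
    "select_variables",
    "two_stage_fit",
    "loo_two_stage_responses",
]


@dataclass(frozen=True)
class VIPScores:
    scores: np.ndarray  # one non-negative score per variable
    n_components_used: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, float))


@dataclass
class SelectionResult:
    """Outcome of the two-stage workflow: both models and the kept columns."""

    selected_indices: list[int]
    threshold: float
    stage1_model: PLSModel
    stage2_model: PLSModel
    vip: VIPScores


def compute_vip(model: PLSModel) -> VIPScores:
    """VIP scores of a fitted model (weights are already unit-norm)."""
    W = model.weights
    p = W.shape[0]
    # SSY_a on the original y scale; the ledger stores it as a percentage
    ssy = np.asarray(model.variance_ledger.y_partial, float)
    total = ssy.sum()
    if total <= 0.0:
        raise UndefinedVIPError("no response variance explained by any component")
    scores = np.sqrt(p * (W**2 @ ssy) / total)
    return VIPScores(scores=scores, n_components_used=model.n_components)


def select_variables(vip: VIPScores, threshold: float = 1.0) -> list[int]:
    """Indices with VIP strictly greater than the threshold, original order."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return [int(j) for j in np.flatnonzero(vip.scores > threshold)]


def two_stage_fit(
    X: np.ndarray,
    y: np.ndarray,
    A_stage1: int,
    A_stage2: int | None = None,
    threshold: float = 1.0,
    center: bool = False,
) -> SelectionResult:
    """Full-matrix fit -> VIP -> selection -> reduced-matrix refit.

    Raises
    ------
    SelectionFailureError
        If no variable exceeds the VIP threshold; lower the threshold.
    """
    X = np.asarray(X, dtype=float)
    if A_stage2 is None:
        A_stage2 = A_stage1
    stage1 = fit_pls(X, y, A_stage1, center=center)
    vip = compute_vip(stage1)
    selected = select_variables(vip, threshold)
    if not selected:
        raise SelectionFailureError(
            f"no variable has VIP > {threshold}; lower the threshold"
        )
    A2 = min(int(A_stage2), len(selected), X.shape[0])
    stage2 = fit_pls(X[:, selected], y, A2, center=center)
    return SelectionResult(
        selected_indices=selected,
        threshold=float(threshold),
        stage1_model=stage1,
        stage2_model=stage2,
        vip=vip,
    )


def loo_two_stage_responses(
    X: np.ndarray,
    y: np.ndarray,
    A_stage1: int,
    A_stage2: int | None = None,
    threshold: float = 1.0,
    center: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out calculated responses for both stages.

    For each subject, the full fit-select-refit workflow is rerun on the
    remaining subjects and the held-out subject's response is predicted.
    This is the honest (out-of-sample) counterpart to the in-sample
    responses used by the class-modeling layer: with many more variables
    than subjects, in-sample responses separate the classes almost
    perfectly even under a null effect, so any generalization claim needs
    this mode.  Returns ``(stage1_loo, stage2_loo)`` response vectors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    yh1 = np.zeros(n)
    yh2 = np.zeros(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        sel = two_stage_fit(
            X[mask], y[mask], A_stage1, A_stage2, threshold=threshold, center=center
        )
        yh1[i] = predict(sel.stage1_model, X[i : i + 1])[0]
        yh2[i] = predict(sel.stage2_model, X[i : i + 1, sel.selected_indices])[0]
    return yh1, yh2
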