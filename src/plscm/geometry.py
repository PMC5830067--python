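"""Rotated two-LV score projections and the separating-vertical-line search.

A pair of latent-variable scores spans a plane; rotating that plane
counterclockwise by an angle theta and asking whether a vertical line
separates the two classes is equivalent to asking for a separating
direction within the plane.  The search scans [0, 180) degrees — a vertical
separator is invariant under a half turn with the sides swapped — and among
separating angles keeps the one maximizing the margin (the gap between the
class extremes along the rotated first coordinate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScoreProjection", "rotate_scores", "find_separating_rotation"]


@dataclass(frozen=True)
class ScoreProjection:
    component_pair: tuple[int, int]  # 1-based LV indices
    angle_deg: float
    rotated_scores: np.ndarray  # n x 2
    separating_value: float | None
    perfectly_separated: bool
    margin: float = float("nan")


def _pair_columns(T: np.ndarray, pair: tuple[int, int]) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    a, b = pair
    A = T.shape[1]
    if a == b:
        raise ValueError("component pair must use two distinct LVs")
    if not (1 <= a <= A and 1 <= b <= A):
        raise ValueError(f"component indices must be in 1..{A}, got {pair}")
    return T[:, [a - 1, b - 1]]


def rotate_scores(
    T: np.ndarray, pair: tuple[int, int], angle_deg: float
) -> ScoreProjection:
    """Counterclockwise rotation of the selected two score columns."""
    Z = _pair_columns(T, pair)
    th = np.deg2rad(angle_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return ScoreProjection(
        component_pair=(int(pair[0]), int(pair[1])),
        angle_deg=float(angle_deg),
        rotated_scores=Z @ R.T,
        separating_value=None,
        perfectly_separated=False,
    )


def _margin_and_split(x: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Gap between class extremes along x (positive iff separated), midpoint."""
    x0, x1 = x[labels == 0], x[labels == 1]
    # class 0 left of class 1, or mirrored
    gap_a = x1.min() - x0.max()
    gap_b = x0.min() - x1.max()
    if gap_a >= gap_b:
        return float(gap_a), float((x0.max() + x1.min()) / 2.0)
    return float(gap_b), float((x1.max() + x0.min()) / 2.0)


def find_separating_rotation(
    T: np.ndarray,
    labels: np.ndarray,
    pair: tuple[int, int] = (2, 3),
    step_deg: float = 0.5,
) -> ScoreProjection:
    """Grid-search the rotation whose vertical line best separates the classes.

    Returns the max-margin projection; ``perfectly_separated`` is False when
    no angle on the grid achieves a positive gap, in which case the returned
    separating value is still the best-gap midpoint (useful for plotting).
    """
    labels = np.asarray(labels, dtype=int).ravel()
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both classes must be present")
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    Z = _pair_columns(T, pair)
    angles = np.arange(0.0, 180.0, step_deg)
    best = (-np.inf, 0.0, 0.0)  # margin, angle, split value
    for ang in angles:
        th = np.deg2rad(ang)
        # rotated first coordinate only
        x = Z[:, 0] * np.cos(th) - Z[:, 1] * np.sin(th)
        margin, split = _margin_and_split(x, labels)
        if margin > best[0]:
            best = (margin, ang, split)
    margin, ang, split = best
    proj = rotate_scores(T, pair, ang)
    return ScoreProjection(
        component_pair=proj.component_pair,
        angle_deg=ang,
        rotated_scores=proj.rotated_scores,
        separating_value=split,
        perfectly_separated=bool(margin > 0.0),
        margin=margin,
    )
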