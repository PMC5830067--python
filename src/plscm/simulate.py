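"""Synthetic two-class immunophenotype cohorts and CD4 trajectories.

The study-scale cohorts this package analyses were never deposited, so the
generator provides a stated statistical world with the same shape: a small
two-class cohort (22 vs 14 subjects by default, or 36 vs 14 for the
patients-versus-healthy design) by 350 percentage variables, a sparse set
of truly discriminative variables, correlation blocks driven by shared
latent factors, and — crucially for the uncentered analysis — per-variable
baseline levels far from zero, so the vector of variable means dominates
the uncentered sum of squares and the first latent variable of an
uncentered PLS fit absorbs it.

Each variable j has a baseline level b_j (drawn once per cohort), a
within-class standard deviation s_j, and, if informative, a class-mean
shift of ``effect_size`` x s_j.  The value for subject i is

    x_ij = b_j + s_j * ( sqrt(f) * g_j * F_{i,k(j)} + sqrt(1-f) * e_ij )
              + effect_size * s_j * d_j * y_i

with F the per-subject latent factors (one of ``n_latent_factors`` blocks
per variable), f the shared-variance fraction, g_j and d_j random signs,
and e independent standard normal noise.  Values are clipped to [0, 100];
the clipping rate is monitored and a configuration warning is raised when
it exceeds 10%, since heavy clipping would distort the planted effects.

All randomness fans out from one integer seed into independent substreams
(baselines, factor structure, factors, noise, shifts), so changing one
block's parameters does not perturb the draws of the others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import CD4Trajectory, ClassCoding, PhenotypeMatrix

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_trajectories",
]


class ClippingWarning(UserWarning):
    """More than the tolerated fraction of values hit the [0, 100] bounds."""


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Statistical recipe for one synthetic cohort.

    Defaults mirror the case-control design (22 controls vs 14 cases); use
    ``n_class0=36, n_class1=14`` for the patients-versus-healthy design.
    ``effect_size`` is the class-mean shift in units of within-class SD.
    """

    n_class0: int = 22
    n_class1: int = 14
    n_variables: int = 350
    n_informative: int = 30
    effect_size: float = 1.5
    n_latent_factors: int = 3
    factor_strength: float = 0.4
    baseline_mean_range: tuple[float, float] = (10.0, 70.0)
    noise_sd_range: tuple[float, float] = (1.0, 6.0)
    seed: int = 0
    clip_warn_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_class0 < 1 or self.n_class1 < 1:
            raise ValueError("both class sizes must be positive")
        if not (0 <= self.n_informative <= self.n_variables):
            raise ValueError("n_informative must be in [0, n_variables]")
        if not (0.0 <= self.factor_strength < 1.0):
            raise ValueError("factor_strength must be in [0, 1)")
        lo, hi = self.baseline_mean_range
        if not (0.0 <= lo <= hi <= 100.0):
            raise ValueError("baseline_mean_range must lie within [0, 100]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth, for recovery tests and reports."""

    informative_indices: np.ndarray
    true_effects: np.ndarray  # per-variable mean shift on the percentage scale
    factor_loadings: np.ndarray  # variables x factors
    clip_fraction: float = 0.0


def _substreams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {nm: np.random.default_rng(ss) for nm, ss in zip(names, children)}


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[PhenotypeMatrix, SyntheticTruth]:
    """Draw one cohort; deterministic given ``config.seed``."""
    cfg = config
    rngs = _substreams(
        cfg.seed, ("baseline", "structure", "factors", "noise", "shifts")
    )
    n = cfg.n_class0 + cfg.n_class1
    p = cfg.n_variables
    y = np.concatenate(
        [np.zeros(cfg.n_class0, dtype=int), np.ones(cfg.n_class1, dtype=int)]
    )

    baselines = rngs["baseline"].uniform(*cfg.baseline_mean_range, size=p)
    sds = rngs["baseline"].uniform(*cfg.noise_sd_range, size=p)

    # block structure: each variable tied to one latent factor, random sign
    k = max(cfg.n_latent_factors, 1)
    block = rngs["structure"].integers(0, k, size=p)
    sign = rngs["structure"].choice([-1.0, 1.0], size=p)
    informative = np.sort(
        rngs["structure"].choice(p, size=cfg.n_informative, replace=False)
    )
    d_sign = rngs["shifts"].choice([-1.0, 1.0], size=cfg.n_informative)

    F = rngs["factors"].standard_normal((n, k))
    E = rngs["noise"].standard_normal((n, p))

    f = cfg.factor_strength
    factor_part = np.sqrt(f) * F[:, block] * sign if cfg.n_latent_factors > 0 else 0.0
    values = baselines + sds * (factor_part + np.sqrt(1.0 - f) * E)

    effects = np.zeros(p)
    effects[informative] = cfg.effect_size * sds[informative] * d_sign
    values = values + np.outer(y, effects)

    clipped = (values < 0.0) | (values > 100.0)
    clip_fraction = float(clipped.mean())
    values = np.clip(values, 0.0, 100.0)
    if clip_fraction > cfg.clip_warn_fraction:
        warnings.warn(
            f"{clip_fraction:.1%} of values clipped to [0, 100]; planted "
            "effects are distorted — adjust baseline or noise ranges",
            ClippingWarning,
            stacklevel=2,
        )

    loadings = np.zeros((p, k))
    loadings[np.arange(p), block] = np.sqrt(f) * sign * sds

    matrix = PhenotypeMatrix(
        values=values,
        subject_ids=[f"S{i:03d}" for i in range(n)],
        variable_names=[f"V{j:03d}" for j in range(p)],
        class_labels=y,
        coding=ClassCoding("class0", "class1"),
    )
    truth = SyntheticTruth(
        informative_indices=informative,
        true_effects=effects,
        factor_loadings=loadings,
        clip_fraction=clip_fraction,
    )
    return matrix, truth


def generate_trajectories(
    n_cases: int,
    n_controls: int,
    visits: int = 8,
    years: float = 10.0,
    case_slope: float = -66.0,
    baseline_count: float = 1000.0,
    noise_sd: float = 50.0,
    seed: int = 0,
) -> tuple[list[CD4Trajectory], list[str]]:
    """CD4 time series: controls flat, cases declining at ``case_slope``.

    The default decline of -66 cells/uL per year matches the median slope
    observed in progressing elite controllers.  Returns the trajectories
    and the true category per subject ("case" or "control").
    """
    if visits < 3:
        raise ValueError("need >= 3 visits")
    if n_cases < 0 or n_controls < 0 or n_cases + n_controls == 0:
        raise ValueError("subject counts must be non-negative and not both zero")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    times = np.linspace(0.0, years, visits)
    out: list[CD4Trajectory] = []
    truth: list[str] = []
    specs = [("case", case_slope)] * n_cases + [("control", 0.0)] * n_controls
    for i, (label, slope) in enumerate(specs):
        counts = baseline_count + slope * times + rng.normal(0.0, noise_sd, visits)
        counts = np.maximum(counts, 1.0)  # CD4 counts are positive
        out.append(
            CD4Trajectory(subject_id=f"T{i:03d}", times=times.copy(), counts=counts)
        )
        truth.append(label)
    return out, truth
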