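"""Core data containers shared by every pipeline stage.

The central object is :class:`PhenotypeMatrix`: a subjects-by-variables
table of immunophenotype percentages (T-cell subset frequencies in
[0, 100]) together with a binary class code per subject.  The same matrix
serves both case-control designs analysed by the pipeline — elite
controllers (EC) versus healthy controls, and EC cases (declining CD4)
versus EC controls (stable CD4) — by swapping the :class:`ClassCoding`
legend rather than relabelling columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

__all__ = ["PhenotypeMatrix", "ClassCoding", "CD4Trajectory"]


@dataclass(frozen=True)
class ClassCoding:
    """Legend mapping the binary 0/1 response code to human-readable labels."""

    label_for_zero: str = "class0"
    label_for_one: str = "class1"

    def __post_init__(self) -> None:
        if self.label_for_zero == self.label_for_one:
            raise ValidationError("class labels for codes 0 and 1 must differ")

    def label(self, code: int) -> str:
        return self.label_for_one if code == 1 else self.label_for_zero


@dataclass
class PhenotypeMatrix:
    """Subjects x variables percentage matrix with a binary class label.

    Parameters
    ----------
    values
        Array of shape ``(n_subjects, n_variables)``; every entry must be
        finite and lie in ``[0, 100]`` (percent of parent population).
    subject_ids
        Unique identifier per row.
    variable_names
        Unique subset label per column.
    class_labels
        Per-subject binary code (0 or 1); both classes must be present.
    coding
        Optional legend for the 0/1 codes.
    """

    values: np.ndarray
    subject_ids: list[str]
    variable_names: list[str]
    class_labels: np.ndarray
    coding: ClassCoding = field(default_factory=ClassCoding)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.class_labels = np.asarray(self.class_labels, dtype=int)
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.variable_names = [str(v) for v in self.variable_names]
        self._validate()

    def _validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.subject_ids) != n:
            raise ValidationError(
                f"{len(self.subject_ids)} subject ids for {n} rows"
            )
        if len(self.variable_names) != p:
            raise ValidationError(
                f"{len(self.variable_names)} variable names for {p} columns"
            )
        if len(set(self.subject_ids)) != n:
            dupes = sorted(
                {s for s in self.subject_ids if self.subject_ids.count(s) > 1}
            )
            raise ValidationError(f"duplicate subject ids: {dupes}")
        if len(set(self.variable_names)) != p:
            dupes = sorted(
                {v for v in self.variable_names if self.variable_names.count(v) > 1}
            )
            raise ValidationError(f"duplicate variable names: {dupes}")
        bad = ~np.isfinite(self.values)
        bad |= (self.values < 0.0) | (self.values > 100.0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"value {self.values[i, j]!r} out of [0, 100] at "
                f"row '{self.subject_ids[i]}', column '{self.variable_names[j]}'"
            )
        if self.class_labels.shape != (n,):
            raise ValidationError("class_labels length must match row count")
        labels = set(self.class_labels.tolist())
        if not labels <= {0, 1}:
            raise ValidationError(f"class labels must be 0/1, got {sorted(labels)}")
        if labels != {0, 1}:
            raise ValidationError("both classes must be non-empty")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def subset_variables(self, indices: list[int]) -> "PhenotypeMatrix":
        """Return a new matrix restricted to the given columns (order kept)."""
        idx = list(indices)
        return PhenotypeMatrix(
            values=self.values[:, idx],
            subject_ids=list(self.subject_ids),
            variable_names=[self.variable_names[j] for j in idx],
            class_labels=self.class_labels.copy(),
            coding=self.coding,
        )


@dataclass
class CD4Trajectory:
    """Longitudinal CD4 counts for one subject.

    ``times`` are years since baseline (strictly increasing, >= 0) and
    ``counts`` are CD4 cells/uL (> 0).  At least three visits are required
    for the slope regression to be meaningful.
    """

    subject_id: str
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.counts.shape:
            raise ValidationError("times and counts must be 1-D and equal length")
        if len(self.times) < 3:
            raise ValidationError(
                f"subject '{self.subject_id}': need >= 3 visits, got {len(self.times)}"
            )
        if np.any(self.times < 0):
            raise ValidationError(f"subject '{self.subject_id}': negative time")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"subject '{self.subject_id}': times must be strictly increasing"
            )
        if np.any(self.counts <= 0) or not np.all(np.isfinite(self.counts)):
            raise ValidationError(
                f"subject '{self.subject_id}': counts must be positive and finite"
            )

    @property
    def n_visits(self) -> int:
        return len(self.times)
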