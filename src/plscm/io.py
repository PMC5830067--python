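"""Readers and writers for the pipeline's tabular formats.

Phenotype CSV layout: a header row, first column the subject id, second
column the 0/1 class code, remaining columns the percentage variables.
Trajectory CSV layout: long format with columns ``subject_id``,
``time_years``, ``cd4_count``.  All files are comma-separated UTF-8 with a
decimal point.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .class_model import ClassDensityModel, OperatingPoint, RiskCurve
from .data import CD4Trajectory, ClassCoding, PhenotypeMatrix
from .exceptions import FormatError, ValidationError
from .pls import VarianceLedger

__all__ = [
    "read_phenotype_csv",
    "write_phenotype_csv",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "write_report",
]


def read_phenotype_csv(path, coding: ClassCoding | None = None) -> PhenotypeMatrix:
    """Read and validate a phenotype CSV (see module docstring for layout)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, header=0, dtype={0: str}, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] < 3:
        raise FormatError(
            f"{path}: need id, class and at least one variable column"
        )
    subject_ids = df.iloc[:, 0].astype(str).tolist()
    variable_names = [str(c) for c in df.columns[2:]]
    if len(set(subject_ids)) != len(subject_ids):
        raise FormatError(f"{path}: duplicate subject ids")
    if len(set(variable_names)) != len(variable_names):
        raise FormatError(f"{path}: duplicate variable names")

    labels_raw = df.iloc[:, 1]
    try:
        labels = labels_raw.astype(int).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-integer class label") from exc

    block = df.iloc[:, 2:]
    values = block.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.isfinite(values)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValidationError(
            f"{path}: non-numeric or missing value at row "
            f"'{subject_ids[i]}', column '{variable_names[j]}'"
        )
    kwargs = {"coding": coding} if coding is not None else {}
    return PhenotypeMatrix(
        values=values,
        subject_ids=subject_ids,
        variable_names=variable_names,
        class_labels=labels,
        **kwargs,
    )


def write_phenotype_csv(matrix: PhenotypeMatrix, path) -> Path:
    """Write a matrix in the standard layout; full float precision."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, columns=matrix.variable_names)
    df.insert(0, "class", matrix.class_labels)
    df.insert(0, "subject_id", matrix.subject_ids)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trajectories_csv(path) -> list[CD4Trajectory]:
    """Read long-format CD4 series; one trajectory per subject, time-sorted."""
    path = Path(path)
    df = pd.read_csv(path, header=0)
    required = {"subject_id", "time_years", "cd4_count"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: need columns {sorted(required)}, got {list(df.columns)}"
        )
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("time_years")
        out.append(
            CD4Trajectory(
                subject_id=str(sid),
                times=grp["time_years"].to_numpy(dtype=float),
                counts=grp["cd4_count"].to_numpy(dtype=float),
            )
        )
    return out


def write_trajectories_csv(trajectories: list[CD4Trajectory], path) -> Path:
    path = Path(path)
    rows = []
    for tr in trajectories:
        for t, c in zip(tr.times, tr.counts):
            rows.append({"subject_id": tr.subject_id, "time_years": t, "cd4_count": c})
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_report(results: dict, outdir) -> dict[str, str]:
    """Write whichever report tables are present in ``results``.

    Recognized keys (all optional except ``variance_ledger``):

    - ``variance_ledger`` (:class:`VarianceLedger`) -> ``variance_table.csv``
      in the partial/total x X-block/y-block layout
    - ``selected_variables`` (DataFrame-able records with at least
      variable_name, vip_score, selected) -> ``selected_variables.csv``
    - ``class_densities`` (:class:`ClassDensityModel`) ->
      ``class_densities.csv``
    - ``risk_curve`` (:class:`RiskCurve`) -> ``risk_curve.csv``
    - ``operating_point`` (:class:`OperatingPoint`) ->
      ``operating_point.json``
    - ``screen`` (records) -> ``univariate_screen.csv``
    - ``projection`` (dict with rotated scores et al.) ->
      ``score_projection.csv`` + angle/split inside the summary
    - ``summary`` (JSON-able dict) -> ``run_summary.json``

    Returns a manifest mapping logical names to written file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    ledger = results.get("variance_ledger")
    if ledger is None:
        raise ValueError("results must include a variance_ledger")
    assert isinstance(ledger, VarianceLedger)
    path = outdir / "variance_table.csv"
    pd.DataFrame(ledger.as_table()).to_csv(path, index=False, float_format="%.6g")
    manifest["variance_table"] = str(path)

    sel = results.get("selected_variables")
    if sel is not None:
        path = outdir / "selected_variables.csv"
        pd.DataFrame(sel).to_csv(path, index=False, float_format="%.10g")
        manifest["selected_variables"] = str(path)

    dens = results.get("class_densities")
    if dens is not None:
        assert isinstance(dens, ClassDensityModel)
        path = outdir / "class_densities.csv"
        pd.DataFrame(
            [
                {"class": 0, "mean": dens.mu0, "sd": dens.sigma0,
                 "normality_p": dens.normality_p0},
                {"class": 1, "mean": dens.mu1, "sd": dens.sigma1,
                 "normality_p": dens.normality_p1},
            ]
        ).to_csv(path, index=False, float_format="%.10g")
        manifest["class_densities"] = str(path)

    curve = results.get("risk_curve")
    if curve is not None:
        assert isinstance(curve, RiskCurve)
        path = outdir / "risk_curve.csv"
        pd.DataFrame(
            {
                "threshold": curve.thresholds,
                "alpha": curve.alpha,
                "beta": curve.beta,
            }
        ).to_csv(path, index=False, float_format="%.10g")
        manifest["risk_curve"] = str(path)

    point = results.get("operating_point")
    if point is not None:
        assert isinstance(point, OperatingPoint)
        path = outdir / "operating_point.json"
        path.write_text(
            json.dumps(
                {
                    "threshold": point.threshold,
                    "alpha": point.alpha,
                    "beta": point.beta,
                    "sensitivity": point.sensitivity,
                    "specificity": point.specificity,
                    "sensitivity_pct": point.sensitivity_pct,
                    "specificity_pct": point.specificity_pct,
                },
                indent=2,
            )
            + "\n"
        )
        manifest["operating_point"] = str(path)

    screen = results.get("screen")
    if screen is not None:
        path = outdir / "univariate_screen.csv"
        pd.DataFrame(screen).to_csv(path, index=False, float_format="%.10g")
        manifest["univariate_screen"] = str(path)

    proj = results.get("projection")
    if proj is not None:
        path = outdir / "score_projection.csv"
        pd.DataFrame(proj).to_csv(path, index=False, float_format="%.10g")
        manifest["score_projection"] = str(path)

    summary = results.get("summary")
    if summary is not None:
        path = outdir / "run_summary.json"
        path.write_text(json.dumps(summary, indent=2, default=_jsonable) + "\n")
        manifest["run_summary"] = str(path)

    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
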