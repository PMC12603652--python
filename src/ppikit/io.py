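"""File round-tripping: numeric TSV, task JSON, result/manifest JSON.

TSV (tab-delimited, '.' decimal) is the sole numeric exchange format:
no header gives a plain T-by-V matrix; an optional single header row
names the voxel columns.  Missing values are not permitted.  All JSON
artifacts embed a schema version and the configuration/seed needed to
regenerate them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core_timeseries import BasisSet, RoiMatrix, TimeSeries
from .errors import InvalidArgumentError
from .ppi_design import FitResult, PsychRegressor
from .synthetic_data import GroundTruth, SubjectData

SCHEMA_VERSION = 1

#: float format that round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


def _parse_tsv(path) -> tuple[list[str] | None, np.ndarray]:
    path = Path(path)
    raw = [
        (i + 1, line.rstrip("\n").rstrip("\r"))
        for i, line in enumerate(path.read_text().splitlines())
        if line.strip() != ""
    ]
    if not raw:
        raise InvalidArgumentError(f"{path}: file is empty")
    header: list[str] | None = None
    first_cells = raw[0][1].split("\t")
    try:
        [float(c) for c in first_cells]
    except ValueError:
        header = [c.strip() for c in first_cells]
        raw = raw[1:]
        if not raw:
            raise InvalidArgumentError(f"{path}: no data rows after header")
    n_cols = len(raw[0][1].split("\t"))
    data = np.empty((len(raw), n_cols))
    for r, (lineno, line) in enumerate(raw):
        cells = line.split("\t")
        if len(cells) != n_cols:
            raise InvalidArgumentError(
                f"{path}: row {lineno} has {len(cells)} columns, expected {n_cols}"
            )
        for j, cell in enumerate(cells):
            try:
                data[r, j] = float(cell)
            except ValueError:
                raise InvalidArgumentError(
                    f"{path}: could not parse value at row {lineno}, column {j + 1}: {cell!r}"
                ) from None
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[0]
        raise InvalidArgumentError(
            f"{path}: non-finite value at row {bad[0] + 1}, column {bad[1] + 1}"
        )
    return header, data


def read_timeseries_tsv(path, tr: float) -> TimeSeries | RoiMatrix:
    """Read a numeric TSV as a TimeSeries (1 column) or RoiMatrix (V > 1).

    A single non-numeric header row of voxel labels is permitted and
    skipped; parse failures name the offending row and column.
    """
    _, data = _parse_tsv(path)
    if data.shape[1] == 1:
        return TimeSeries(data[:, 0], tr)
    return RoiMatrix(data, tr)


def write_timeseries_tsv(obj, path) -> None:
    """Write a TimeSeries/RoiMatrix/array to TSV at full double precision."""
    v = obj.values if isinstance(obj, (TimeSeries, RoiMatrix)) else np.asarray(obj, float)
    if v.ndim == 1:
        v = v[:, None]
    np.savetxt(path, v, delimiter="\t", fmt=_FLOAT_FMT)


def boxcar_from_onsets(onsets_s, durations_s, tr: float, n_scans: int) -> PsychRegressor:
    """Build a 0/1 task regressor from onset/duration lists (seconds)."""
    onsets = np.asarray(onsets_s, dtype=float)
    durations = np.asarray(durations_s, dtype=float)
    if onsets.shape != durations.shape:
        raise InvalidArgumentError("onsets and durations must have equal length")
    t = np.arange(n_scans) * tr
    values = np.zeros(n_scans)
    for onset, dur in zip(onsets, durations):
        values[(t >= onset) & (t < onset + dur)] = 1.0
    return PsychRegressor(values=values, onsets_s=list(onsets), durations_s=list(durations))


def read_task_json(path) -> PsychRegressor:
    """Read a task specification JSON: {onsets_s, durations_s, tr, n_scans}."""
    spec = json.loads(Path(path).read_text())
    for key in ("onsets_s", "durations_s", "tr", "n_scans"):
        if key not in spec:
            raise InvalidArgumentError(f"task JSON missing required key {key!r}")
    return boxcar_from_onsets(
        spec["onsets_s"], spec["durations_s"], float(spec["tr"]), int(spec["n_scans"])
    )


def write_fit_results_json(fits: dict[str, FitResult], path, config: dict | None = None,
                           extra: dict | None = None) -> None:
    """Serialize per-target fit results with the full configuration echo."""
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "ppi_fit_results",
        "config": config or {},
        "targets": {name: fit.to_dict() for name, fit in fits.items()},
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_fit_results_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "ppi_fit_results":
        raise InvalidArgumentError(f"{path}: not a ppi_fit_results JSON")
    return payload


def fit_result_from_dict(d: dict) -> FitResult:
    """Rebuild a FitResult from its JSON form."""
    labels = list(d.get("labels", d["coefficients"]))
    get = lambda key: np.array([d["coefficients"][lab][key] for lab in labels])
    return FitResult(
        labels=labels,
        beta=get("beta"),
        se=get("se"),
        t=get("t"),
        p=get("p"),
        residual_variance=float(d["residual_variance"]),
        dof=int(d["dof"]),
        rho_used=float(d["rho_used"]),
    )


def write_report_json(report, path) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "kind": "pipeline_report",
    }
    payload.update(report.to_dict())
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_subject_dir(data: SubjectData, path) -> None:
    """Write one subject as a directory of TSVs plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_timeseries_tsv(data.roi, path / "roi.tsv")
    write_timeseries_tsv(data.psy.values, path / "psy.tsv")
    for name, ts in data.targets.items():
        write_timeseries_tsv(ts, path / f"target_{name}.tsv")
    confound_labels: list[str] = []
    if data.confounds is not None and data.confounds.n_columns:
        write_timeseries_tsv(data.confounds.columns, path / "confounds.tsv")
        confound_labels = list(data.confounds.labels)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "kind": "subject_data",
        "tr": data.roi.tr,
        "n_scans": data.roi.n_scans,
        "seed": data.seed_value,
        "targets": sorted(data.targets),
        "confound_labels": confound_labels,
        "truth": data.truth.to_dict() if data.truth is not None else None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_subject_dir(path) -> SubjectData:
    """Load a subject directory written by :func:`write_subject_dir`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    if manifest.get("kind") != "subject_data":
        raise InvalidArgumentError(f"{path}: manifest is not a subject_data manifest")
    tr = float(manifest["tr"])
    roi = read_timeseries_tsv(path / "roi.tsv", tr)
    if isinstance(roi, TimeSeries):
        roi = RoiMatrix(roi.values[:, None], tr)
    _, psy_values = _parse_tsv(path / "psy.tsv")
    psy = PsychRegressor(values=psy_values[:, 0])
    targets = {}
    for name in manifest["targets"]:
        ts = read_timeseries_tsv(path / f"target_{name}.tsv", tr)
        targets[name] = ts if isinstance(ts, TimeSeries) else TimeSeries(ts.values[:, 0], tr)
    confounds = None
    if manifest.get("confound_labels"):
        _, cols = _parse_tsv(path / "confounds.tsv")
        confounds = BasisSet(cols, manifest["confound_labels"])
    truth = GroundTruth.from_dict(manifest["truth"]) if manifest.get("truth") else None
    return SubjectData(
        roi=roi,
        targets=targets,
        psy=psy,
        confounds=confounds,
        truth=truth,
        seed_value=manifest.get("seed"),
    )
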