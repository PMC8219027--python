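"""Readers and writers for the package's plain-text interchange formats.

* localization tables: TSV with header ``x_nm  y_nm  photons  precision_nm``
  (one row per detection); ground truth as a sidecar TSV with
  ``row_index  cluster_id`` (-1 = background);
* ThunderSTORM-style CSV export (``x [nm]``, ``y [nm]``,
  ``intensity [photon]``, ``uncertainty [nm]``), mapped onto the standard
  columns on read; pixel-unit coordinates are converted with a pixel size;
* FP plates and dose-response tables: tidy CSV (``conc_M, replicate,
  signal`` and ``conc_M, arm, replicate, response``);
* cluster exports: CSV of per-cluster metrics plus a JSON stage log.

Schema violations raise ``ValueError`` naming the offending column and the
first offending row, so batch runs fail loudly and actionably.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import AssayConstants, CompetitionIsotherm
from .doseresponse import DoseResponseCurve
from .smlm import REQUIRED_COLUMNS, ClusterSet, cluster_metrics

__all__ = [
    "write_localizations",
    "read_localizations",
    "write_ground_truth",
    "read_ground_truth",
    "read_thunderstorm",
    "write_fp_plate",
    "read_fp_plate",
    "write_dose_response",
    "read_dose_response",
    "export_clusters",
]

_THUNDERSTORM_MAP = {
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "intensity [photon]": "photons",
    "intensity [photons]": "photons",
    "uncertainty [nm]": "precision_nm",
    "uncertainty_xy [nm]": "precision_nm",
}


def _check_numeric(table: pd.DataFrame, columns, path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path}: non-numeric value {table[col].iloc[row]!r} in "
                f"column {col!r} at data row {row}"
            )
        if coerced.isna().any():
            row = int(np.argmax(coerced.isna().to_numpy()))
            raise ValueError(
                f"{path}: missing value in column {col!r} at data row {row}"
            )
        table[col] = coerced
    return table


def write_localizations(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, columns=list(REQUIRED_COLUMNS))


def read_localizations(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing localization columns {missing}")
    return _check_numeric(table, REQUIRED_COLUMNS, path)


def write_ground_truth(labels: np.ndarray, path) -> None:
    pd.DataFrame(
        {"row_index": np.arange(len(labels)), "cluster_id": labels}
    ).to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> np.ndarray:
    table = pd.read_csv(path, sep="\t")
    for col in ("row_index", "cluster_id"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing ground-truth column {col!r}")
    table = _check_numeric(table, ("row_index", "cluster_id"), path)
    return table.sort_values("row_index")["cluster_id"].to_numpy(dtype=int)


def read_thunderstorm(path, pixel_size_nm: float | None = None) -> pd.DataFrame:
    """Read a ThunderSTORM-style CSV localization export.

    When coordinates are in pixels (columns ``x [px]``/``y [px]``), pass
    ``pixel_size_nm`` to convert them into the package's continuous-nm,
    0-based Cartesian frame.
    """
    raw = pd.read_csv(path)
    cols = {c.strip(): c for c in raw.columns}
    table = pd.DataFrame()
    for src, dst in _THUNDERSTORM_MAP.items():
        if src in cols and dst not in table.columns:
            table[dst] = raw[cols[src]]
    if "x_nm" not in table.columns and "x [px]" in cols:
        if pixel_size_nm is None:
            raise ValueError(f"{path}: pixel coordinates need pixel_size_nm")
        table["x_nm"] = raw[cols["x [px]"]] * pixel_size_nm
        table["y_nm"] = raw[cols["y [px]"]] * pixel_size_nm
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: could not map columns for {missing}")
    return _check_numeric(table, REQUIRED_COLUMNS, path)


def write_fp_plate(iso: CompetitionIsotherm, path) -> None:
    rows = [
        {"conc_M": conc, "replicate": rep, "signal": iso.signals[rep, j]}
        for rep in range(iso.n_replicates)
        for j, conc in enumerate(iso.concentrations)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fp_plate(path, assay: AssayConstants | None = None) -> CompetitionIsotherm:
    table = pd.read_csv(path)
    for col in ("conc_M", "replicate", "signal"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing plate column {col!r}")
    table = _check_numeric(table, ("conc_M", "replicate", "signal"), path)
    wide = table.pivot_table(
        index="replicate", columns="conc_M", values="signal", sort=True
    )
    if wide.isna().any().any():
        raise ValueError(f"{path}: replicates do not share the concentration grid")
    return CompetitionIsotherm(
        concentrations=wide.columns.to_numpy(dtype=float),
        signals=wide.to_numpy(),
        assay=assay or AssayConstants(),
    )


def write_dose_response(curves: list[DoseResponseCurve], path) -> None:
    rows = []
    for curve in curves:
        for rep in range(curve.n_replicates):
            for j, dose in enumerate(curve.doses):
                rows.append(
                    {
                        "conc_M": dose,
                        "arm": curve.label or "arm0",
                        "replicate": rep,
                        "response": curve.responses[rep, j],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dose_response(path) -> list[DoseResponseCurve]:
    table = pd.read_csv(path)
    for col in ("conc_M", "arm", "replicate", "response"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing dose-response column {col!r}")
    table = _check_numeric(table, ("conc_M", "replicate", "response"), path)
    curves = []
    for arm, sub in table.groupby("arm", sort=False):
        wide = sub.pivot_table(
            index="replicate", columns="conc_M", values="response", sort=True
        )
        if wide.isna().any().any():
            raise ValueError(f"{path}: arm {arm!r} is not a complete dose grid")
        curves.append(
            DoseResponseCurve(
                doses=wide.columns.to_numpy(dtype=float),
                responses=wide.to_numpy(),
                label=str(arm),
            )
        )
    return curves


def export_clusters(clusters: ClusterSet, csv_path, log_path=None) -> None:
    """Write per-cluster metrics to CSV and the stage log to JSON."""
    if clusters.n_clusters:
        cluster_metrics(clusters).to_csv(csv_path)
    else:
        pd.DataFrame(
            columns=["n_locs", "x_c", "y_c", "extent_nm", "anisotropy", "extended"]
        ).to_csv(csv_path, index_label="cluster_id")
    if log_path is not None:
        Path(log_path).write_text(json.dumps(clusters.stage_log, indent=2))
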