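"""Readers and writers for the pipeline's canonical formats.

TSV (tab-separated, header row) for tabular data, NIfTI-1 for images, JSON
for configuration and provenance. Edge-matrix TSVs carry a direction
convention comment line; time-series round-trips are lossless to 12
significant digits.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import ConfoundTable, TimeSeriesMatrix
from .gca import EdgeMatrix

__all__ = [
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_edge_tsv",
    "write_edge_tsv",
    "read_confounds_tsv",
    "write_confounds_tsv",
    "read_nifti_4d",
    "write_nifti_3d",
    "write_nifti_4d",
    "write_provenance",
]

logger = logging.getLogger(__name__)

DIRECTION_COMMENT = "# direction: values[target_row, source_column] = source -> target"
FLOAT_FMT = "%.12g"


def _check_no_nan(df: pd.DataFrame, path: Path) -> None:
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df.index[df[col].isna()][0])
        raise ValueError(f"missing value in {path} at row {row}, column '{col}'")


def write_timeseries_tsv(ts: TimeSeriesMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(ts.values, columns=ts.channel_names)
    with open(path, "w") as fh:
        fh.write(f"# sampling_interval_seconds: {ts.sampling_interval}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_timeseries_tsv(path: str | Path) -> TimeSeriesMatrix:
    path = Path(path)
    tr = 2.0
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("#"):
        skip = 1
        if "sampling_interval_seconds:" in first:
            tr = float(first.split(":", 1)[1])
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    _check_no_nan(df, path)
    return TimeSeriesMatrix(df.to_numpy(float), tr, list(df.columns))


def write_edge_tsv(edges: EdgeMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(edges.values, index=edges.channel_names,
                      columns=edges.channel_names)
    with open(path, "w") as fh:
        fh.write(DIRECTION_COMMENT + "\n")
        fh.write(f"# band_hz: {edges.band[0]} {edges.band[1]}\n")
        df.to_csv(fh, sep="\t", index=True, index_label="target",
                  float_format=FLOAT_FMT)


def read_edge_tsv(path: str | Path) -> EdgeMatrix:
    path = Path(path)
    band = (0.01, 0.1)
    skip = 0
    has_convention = False
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            if line.strip() == DIRECTION_COMMENT:
                has_convention = True
            elif line.startswith("# band_hz:"):
                lo, hi = line.split(":", 1)[1].split()
                band = (float(lo), float(hi))
    if not has_convention:
        warnings.warn(
            f"{path} lacks the direction-convention comment; assuming "
            "source-column / target-row", stacklevel=2,
        )
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0)
    _check_no_nan(df, path)
    return EdgeMatrix(df.to_numpy(float), band=band, channel_names=list(df.columns))


def write_confounds_tsv(conf: ConfoundTable, path: str | Path) -> None:
    cols = {"framewise_displacement": conf.fd, "std_dvars": conf.std_dvars}
    if conf.noise_series is not None:
        for i in range(conf.noise_series.shape[1]):
            cols[f"noise_roi_{i:03d}"] = conf.noise_series[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_confounds_tsv(path: str | Path) -> ConfoundTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _check_no_nan(df, path)
    noise_cols = [c for c in df.columns if c.startswith("noise_roi_")]
    noise = df[noise_cols].to_numpy(float) if noise_cols else None
    return ConfoundTable(
        fd=df["framewise_displacement"].to_numpy(float),
        std_dvars=df["std_dvars"].to_numpy(float),
        noise_series=noise,
    )


def write_nifti_4d(img: np.ndarray, path: str | Path,
                   affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(img, dtype=np.float32), affine), str(path))


write_nifti_3d = write_nifti_4d  # same mechanics; dimensionality from the array


def read_nifti_4d(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def write_provenance(record: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
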