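"""File formats: TIFF movies, HDF5 calibration containers and tables.

Movies travel as multi-page TIFF (16-bit unsigned or float), calibration
maps and localization/candidate tables as HDF5, with CSV mirrors for
interoperability.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationMap
from .movie import CameraMovie

__all__ = [
    "read_movie",
    "write_movie",
    "read_calibration",
    "write_calibration",
    "read_table",
    "write_table",
]

_CALIB_FORMAT = "scmosfit-calibration-1"
_REQUIRED_DATASETS = ("offset", "variance", "gain", "rqe")


def write_movie(movie: CameraMovie, path: str | Path) -> None:
    """Write a frame stack as a multi-page TIFF (lossless for its dtype)."""
    meta = {}
    if movie.pixel_size_nm is not None:
        meta["pixel_size_nm"] = movie.pixel_size_nm
    tifffile.imwrite(path, movie.frames, metadata=meta, photometric="minisblack")


def read_movie(path: str | Path) -> CameraMovie:
    """Read a multi-page TIFF stack into a :class:`CameraMovie`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            pixel_size = None
            if tif.shaped_metadata:
                pixel_size = tif.shaped_metadata[0].get("pixel_size_nm")
    except Exception as err:  # corrupt / truncated file
        raise OSError(f"could not read TIFF movie {path}: {err}") from err
    if frames.ndim == 2:
        frames = frames[None]
    return CameraMovie(frames=frames, pixel_size_nm=pixel_size)


def write_calibration(calib: CalibrationMap, path: str | Path) -> None:
    """Write a calibration container with its summary statistics as attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _CALIB_FORMAT
        for name in _REQUIRED_DATASETS:
            f.create_dataset(name, data=getattr(calib, name))
        if calib.intercept is not None:
            f.create_dataset("intercept", data=calib.intercept)
        for key, value in calib.summary().items():
            f.attrs[key] = value
        if calib.pixel_size_nm is not None:
            f.attrs["pixel_size_nm"] = calib.pixel_size_nm


def read_calibration(path: str | Path) -> CalibrationMap:
    """Read a calibration container, validating its schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for name in _REQUIRED_DATASETS:
            if name not in f:
                raise KeyError(f"calibration file {path} is missing dataset {name!r}")
        data = {name: f[name][()] for name in _REQUIRED_DATASETS}
        intercept = f["intercept"][()] if "intercept" in f else None
        pixel_size = f.attrs.get("pixel_size_nm")
        if "mean_gain" not in f.attrs:
            warnings.warn(
                "calibration file has no mean_gain attribute; recomputed from the gain map",
                stacklevel=2,
            )
    return CalibrationMap(
        **data,
        intercept=intercept,
        pixel_size_nm=None if pixel_size is None else float(pixel_size),
    )


def write_table(table: pd.DataFrame, path: str | Path, group: str = "table") -> None:
    """Write a DataFrame as one HDF5 dataset per column (+ attrs)."""
    with h5py.File(path, "w") as f:
        grp = f.create_group(group)
        for col in table.columns:
            values = table[col].to_numpy()
            if values.dtype == object:
                grp.create_dataset(col, data=values.astype("S"))
            else:
                grp.create_dataset(col, data=values)
        grp.attrs["columns"] = json.dumps(list(table.columns))
        for key, value in table.attrs.items():
            if isinstance(value, (int, float, str, bool)):
                grp.attrs[key] = value


def read_table(path: str | Path, group: str = "table") -> pd.DataFrame:
    """Read a table written by :func:`write_table`, columns in order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        grp = f[group]
        columns = json.loads(grp.attrs["columns"])
        data = {}
        for col in columns:
            values = grp[col][()]
            if values.dtype.kind == "S":
                values = values.astype(str)
            data[col] = values
        table = pd.DataFrame(data)
        for key, value in grp.attrs.items():
            if key != "columns":
                table.attrs[key] = value
    return table
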