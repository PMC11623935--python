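"""File interchange: kymographs and XY stacks as TIFF or delimited text.

The supported kymograph layout is time along rows, position along columns
(one scanned line per row).  Acquisition metadata never lives in the image
files; it is supplied as an :class:`~linefrap.core.AcquisitionParams`, either
constructed in code or parsed from a YAML/JSON config.
"""

from __future__ import annotations

import os

import numpy as np
import tifffile

from .core import AcquisitionParams, FrapStack, InvalidInputError, Kymograph

__all__ = ["read_kymograph", "write_kymograph", "read_frap_stack", "acquisition_from_dict"]

_TIFF_EXT = (".tif", ".tiff")


def _load_matrix(path: str) -> np.ndarray:
    ext = os.path.splitext(path)[1].lower()
    if ext in _TIFF_EXT:
        arr = tifffile.imread(path)
    else:
        with open(path) as fh:
            first = fh.readline()
        delim = "," if "," in first else ("\t" if "\t" in first else None)
        arr = np.loadtxt(path, delimiter=delim)
    return np.asarray(arr, dtype=float)


def read_kymograph(
    path: str,
    params: AcquisitionParams,
    background: float = 0.0,
    meta: dict | None = None,
) -> Kymograph:
    """Read a kymograph (rows = lines in acquisition order, columns = pixels).

    The shape is validated against the declared scan schedule; negative
    intensities are rejected.
    """
    arr = _load_matrix(path)
    if arr.ndim != 2:
        raise InvalidInputError(f"{path}: expected a 2-D matrix, got shape {arr.shape}")
    if params.schedule_declared and arr.shape[0] != params.n_lines:
        raise InvalidInputError(
            f"{path}: shape/schedule mismatch: file has {arr.shape[0]} lines but "
            f"the declared schedule implies {params.n_lines}"
        )
    if np.any(arr < 0):
        raise InvalidInputError(f"{path}: negative intensity values")
    return Kymograph(
        intensities=arr, params=params, background=background, meta=meta or {}
    )


def write_kymograph(path: str, kymo: Kymograph) -> None:
    """Write a kymograph as TIFF or CSV depending on the extension."""
    ext = os.path.splitext(path)[1].lower()
    if ext in _TIFF_EXT:
        tifffile.imwrite(path, kymo.intensities.astype(np.float32))
    else:
        np.savetxt(path, kymo.intensities, delimiter=",", fmt="%.6g")


def read_frap_stack(path: str, params: AcquisitionParams, bleach_roi) -> FrapStack:
    """Read an XY time series (T x Y x X TIFF stack)."""
    arr = tifffile.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 3:
        raise InvalidInputError(f"{path}: expected a 3-D stack, got shape {arr.shape}")
    if params.schedule_declared and arr.shape[0] != params.n_lines:
        raise InvalidInputError(
            f"{path}: stack has {arr.shape[0]} frames but the declared schedule "
            f"implies {params.n_lines}"
        )
    if np.any(arr < 0):
        raise InvalidInputError(f"{path}: negative intensity values")
    return FrapStack(frames=arr, params=params, bleach_roi=tuple(bleach_roi))


def acquisition_from_dict(acq: dict) -> AcquisitionParams:
    """Build AcquisitionParams from the config-file ``acquisition`` block."""
    sched = acq.get("schedule", {}) or {}
    bleach = acq.get("bleach", {}) or {}
    return AcquisitionParams(
        pixel_size=acq.get("pixel_size_um", 0.207),
        line_interval=acq.get("line_interval_s", 1.256e-3),
        n_prebleach=sched.get("pre"),
        n_bleach=sched.get("during"),
        n_postbleach=sched.get("post"),
        bleach_center=bleach.get("center_px"),
        bleach_halfwidth_px=bleach.get("halfwidth_px", 2),
        bleach_duration=bleach.get("duration_s"),
        mode=acq.get("mode", "line"),
        frame_interval=acq.get("frame_interval_s"),
    )
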