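"""File interchange: multi-page TIFF stacks, CSV tables, YAML records.

TIFF is the only image format, CSV the only table format and YAML the only
config/record format used by the package.  Localization tables follow the
ThunderSTORM export header for interoperability.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calibration import ProfileCalibration
from .smlm import LOC_COLUMNS

__all__ = [
    "write_stack",
    "read_stack",
    "write_truth_csv",
    "read_truth_csv",
    "write_locs_csv",
    "read_locs_csv",
    "write_calibration_yaml",
]

_TS_HEADER = {
    "id": "id",
    "frame": "frame",
    "x_nm": "x [nm]",
    "y_nm": "y [nm]",
    "sigma_nm": "sigma [nm]",
    "photons": "intensity [photon]",
    "background_photons": "offset [photon]",
    "uncertainty_nm": "uncertainty [nm]",
}


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (frames, H, W) array as a multi-page float32 TIFF."""
    stack = np.asarray(stack, np.float32)
    if stack.ndim == 2:
        stack = stack[None]
    tifffile.imwrite(str(path), stack, photometric="minisblack")


def read_stack(path) -> np.ndarray:
    stack = tifffile.imread(str(path))
    return stack[None] if stack.ndim == 2 else stack


def write_truth_csv(path, truth: np.ndarray) -> None:
    pd.DataFrame(truth, columns=["frame", "x_nm", "y_nm", "photons"]).to_csv(
        path, index=False
    )


def read_truth_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(float)


def write_locs_csv(path, table: pd.DataFrame) -> None:
    table[LOC_COLUMNS].rename(columns=_TS_HEADER).to_csv(path, index=False)


def read_locs_csv(path) -> pd.DataFrame:
    inv = {v: k for k, v in _TS_HEADER.items()}
    return pd.read_csv(path).rename(columns=inv)


def write_calibration_yaml(path, calib: ProfileCalibration) -> None:
    """Emit the scalar calibration results as YAML plus the per-z CSV next
    to it (same stem, ``.csv``)."""
    record = {
        "tilt_deg": float(calib.tilt_deg),
        "waist_fwhm_um": float(calib.waist_fwhm_um),
        "rayleigh_um": float(calib.rayleigh_um),
        "focus_z_um": float(calib.focus_z_um),
        "efov_um": float(calib.efov_um),
        "flags": {k: (bool(v) if isinstance(v, (bool, np.bool_)) else int(v)) for k, v in calib.flags.items()},
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(record, sort_keys=False))
    pd.DataFrame(
        {
            "z_um": calib.z_um,
            "center_um": calib.center_um,
            "fwhm_um": calib.fwhm_um,
            "fwhm_lateral_um": calib.fwhm_lateral_um,
        }
    ).to_csv(path.with_suffix(".csv"), index=False)
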