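"""File formats: TIFF stacks, localization/trajectory CSV tables, YAML config.

Interchange conventions: lengths in nm and times in seconds in all files
(pixels appear only inside the localizer), CSV for tables, multi-page TIFF
for movies, YAML for configuration, JSON for fitted models.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .emccd import CameraModel

__all__ = [
    "read_stack",
    "write_stack",
    "write_locs",
    "read_locs",
    "read_trajectories",
    "load_camera",
    "load_config",
    "save_model",
    "load_model",
]

LOC_REQUIRED = ["frame", "x_nm", "y_nm"]
TRAJ_REQUIRED = ["traj_id", "frame", "x_nm", "y_nm"]


def read_stack(path):
    """Read a multi-page TIFF as a (frames, rows, cols) float array."""
    try:
        stack = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise IOError(f"{path}: expected a 2D/3D image stack, got shape {stack.shape}")
    return stack.astype(float)


def write_stack(path, stack):
    """Write a stack as multi-page float32 TIFF (round-trips pixel values)."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def _check_columns(df: pd.DataFrame, required, what: str):
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{what} table is missing required column '{col}'")


def write_locs(df: pd.DataFrame, path):
    df.to_csv(path, index=False)


def read_locs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, LOC_REQUIRED, "localization")
    return df


def read_trajectories(path, dt: float, R: float = 1.0 / 6.0):
    """Load trajectory tables into per-trajectory containers.

    Expects columns ``traj_id, frame, x_nm, y_nm`` and optionally
    ``sd_x_nm, sd_y_nm``; rows are sorted by frame within each trajectory.
    Returns a dict ``traj_id -> diffusion.Trajectory`` (``eps2 is None`` when
    the precision columns are absent; estimators that need precisions then
    refuse with a clear error).
    """
    from .diffusion import Trajectory

    df = pd.read_csv(path)
    _check_columns(df, TRAJ_REQUIRED, "trajectory")
    has_sd = "sd_x_nm" in df.columns and "sd_y_nm" in df.columns
    out = {}
    for tid, grp in df.groupby("traj_id"):
        grp = grp.sort_values("frame")
        pos = grp[["x_nm", "y_nm"]].to_numpy(dtype=float)
        eps2 = grp[["sd_x_nm", "sd_y_nm"]].to_numpy(dtype=float) ** 2 if has_sd else None
        out[tid] = Trajectory(positions=pos, dt=dt, eps2=eps2, R=R)
    return out


_CAMERA_KEYS = {"gain", "offset", "readout_sd", "pixel_size_nm"}


def load_camera(block: dict) -> CameraModel:
    """Camera calibration from a YAML mapping; unknown keys are rejected."""
    unknown = set(block) - _CAMERA_KEYS
    if unknown:
        raise ValueError(f"unknown camera config keys: {sorted(unknown)}")
    return CameraModel(
        gain=float(block.get("gain", 50.0)),
        offset=float(block.get("offset", 100.0)),
        readout_sd=float(block.get("readout_sd", 10.0)),
        pixel_size=float(block.get("pixel_size_nm", 80.0)),
    )


_TOP_KEYS = {"camera", "prior", "scenario", "estimator", "seed", "output", "verbosity"}


def load_config(path) -> dict:
    """Validated YAML run configuration; unknown top-level keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "camera" in cfg:
        cfg["camera"] = load_camera(cfg["camera"])
    return cfg


def save_model(model, path, elbo: float | None = None):
    """Serialize a fitted DiffusiveHMM to JSON."""
    payload = {
        "K": int(model.K),
        "D_um2_per_s": np.asarray(model.D).tolist(),
        "A": np.asarray(model.A).tolist(),
        "pi": np.asarray(model.pi).tolist(),
        "dt_s": float(model.dt),
        "tau": float(model.tau),
        "beta": float(model.beta),
        "R": float(model.R),
    }
    if elbo is not None:
        payload["elbo"] = float(elbo)
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path):
    from .hmm import DiffusiveHMM

    d = json.loads(Path(path).read_text())
    return DiffusiveHMM(
        K=d["K"], D=np.asarray(d["D_um2_per_s"]), A=np.asarray(d["A"]),
        pi=np.asarray(d["pi"]), dt=d["dt_s"], tau=d["tau"], beta=d["beta"],
        R=d["R"],
    )
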