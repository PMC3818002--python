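"""File I/O: multi-page float32 TIFF stacks and maps with YAML sidecars.

A phase image stack is stored as a multi-page 32-bit float TIFF, one page
per gain-modulation phase, with acquisition metadata (phases, omega, tau0,
K_phi, seeds) in a ``<stem>.yaml`` sidecar next to it.  Oxygen and
parameter maps are single-page float32 TIFFs; CSV export is provided for
inspection.  Round trips are lossless at float32 precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import tifffile
import yaml

from .core import AcquisitionModel, OxygenMap, PhaseImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_map",
    "read_map",
    "map_to_csv",
    "csv_to_map",
    "write_oxygen_map",
]

PathLike = Union[str, Path]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_stack(stack: PhaseImageStack, path: PathLike) -> None:
    """Write a stack as multi-page float32 TIFF + YAML metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.intensities.astype(np.float32))
    acq = stack.acquisition
    meta = {
        "n_frames": stack.n_frames,
        "phases_rad": [float(v) for v in acq.phases],
        "omega_rad_per_s": float(acq.omega),
        "tau0_s": float(acq.tau0),
        "k_phi_per_mmHg_s": float(acq.k_phi),
    }
    meta.update({k: _yaml_safe(v) for k, v in stack.meta.items()})
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def _yaml_safe(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def read_stack(path: PathLike) -> PhaseImageStack:
    """Read a stack written by :func:`write_stack`, validating frame count."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {side}")
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None]
    meta = yaml.safe_load(side.read_text())
    n_expected = int(meta["n_frames"])
    if data.shape[0] != n_expected:
        raise ValueError(
            f"{path}: {data.shape[0]} frames on disk but sidecar declares "
            f"{n_expected}"
        )
    acq = AcquisitionModel(
        phases=np.asarray(meta["phases_rad"], dtype=float),
        omega=float(meta["omega_rad_per_s"]),
        tau0=float(meta["tau0_s"]),
        k_phi=float(meta["k_phi_per_mmHg_s"]),
    )
    extra = {
        k: v
        for k, v in meta.items()
        if k
        not in (
            "n_frames",
            "phases_rad",
            "omega_rad_per_s",
            "tau0_s",
            "k_phi_per_mmHg_s",
        )
    }
    return PhaseImageStack(intensities=data, acquisition=acq, meta=extra)


def write_map(grid: np.ndarray, path: PathLike) -> None:
    """Write a single 2-D map as float32 TIFF."""
    tifffile.imwrite(Path(path), np.asarray(grid, dtype=np.float32))


def read_map(path: PathLike) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"map file not found: {path}")
    return np.asarray(tifffile.imread(path), dtype=float)


def write_oxygen_map(omap: OxygenMap, path: PathLike) -> None:
    """Write pO2 (float32 TIFF); invalid pixels stored as NaN.

    The vessel mask, if present, goes to ``<stem>_labels.tif`` as uint8.
    """
    path = Path(path)
    po2 = omap.po2.astype(np.float32).copy()
    po2[~omap.valid_mask] = np.nan
    tifffile.imwrite(path, po2)
    if omap.vessel_mask is not None:
        lab = path.with_name(path.stem + "_labels" + path.suffix)
        tifffile.imwrite(lab, omap.vessel_mask.astype(np.uint8))


def map_to_csv(grid: np.ndarray, path: PathLike) -> None:
    """Row-major full-precision CSV export of a 2-D map."""
    np.savetxt(Path(path), np.asarray(grid, dtype=float), delimiter=",",
               fmt="%.17g")


def csv_to_map(path: PathLike) -> np.ndarray:
    return np.loadtxt(Path(path), delimiter=",", ndmin=2)
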