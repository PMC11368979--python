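"""NIfTI volume I/O with a units tag, plus run-configuration plumbing.

Volumes are stored as NIfTI-1 with the voxel size in the header zooms and an
intensity-units tag (``SUV``, ``MBq/mL``, ``MBq*s``, ``mGy`` or ``label``)
in the header ``descrip`` field so a written volume round-trips losslessly.
Label volumes keep their integer dtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = ["VolumeRecord", "RunConfig", "read_volume", "write_volume",
           "load_yaml_config", "write_run_config"]

KNOWN_UNITS = ("SUV", "MBq/mL", "MBq*s", "mGy", "label", "unitless")


@dataclass
class VolumeRecord:
    """3-D array plus voxel size (mm), affine, and an intensity-units tag."""

    array: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    units: str
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 3:
            raise ValueError("expected a 3-D volume")
        if self.units == "label" and not np.issubdtype(self.array.dtype, np.integer):
            raise ValueError("label volumes must be integer typed")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size_mm, 1.0])


def write_volume(record: VolumeRecord, path) -> Path:
    """Write a tagged NIfTI-1 volume; returns the path written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = record.array.dtype
    if record.units == "label":
        dtype = np.int32
    img = nib.Nifti1Image(record.array.astype(dtype), record.affine)
    img.header.set_zooms(record.voxel_size_mm)
    img.header["descrip"] = f"units={record.units}".encode()
    nib.save(img, path)
    return path


def read_volume(path, strict: bool = True) -> VolumeRecord:
    """Read a tagged NIfTI-1 volume; strict mode requires the units tag."""
    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # malformed header or missing file
        raise ValueError(f"cannot read NIfTI volume {path}: {exc}") from exc
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(
        "ascii", "replace"
    )
    units = None
    for part in descrip.split(";"):
        if part.startswith("units="):
            units = part.split("=", 1)[1]
    if units is None:
        if strict:
            raise ValueError(f"volume {path} has no units tag in its header")
        units = "unitless"
    arr = np.asanyarray(img.dataobj)
    if units == "label":
        arr = arr.astype(np.int32)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeRecord(array=arr, voxel_size_mm=zooms, units=units,
                        affine=np.asarray(img.affine))


@dataclass
class RunConfig:
    """Resolved per-run configuration, written next to every run's outputs."""

    scenario: str
    seed: int
    out_dir: str
    profile: str = "full"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"scenario": self.scenario, "seed": self.seed,
                "out_dir": self.out_dir, "profile": self.profile, **self.extra}


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


def write_run_config(run: RunConfig, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "run_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(run.to_dict(), fh, sort_keys=True)
    return path
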