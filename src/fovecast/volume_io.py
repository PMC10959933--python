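"""Volumetric OCT containers and lossless disk I/O.

A macular cube is stored as a 3-D 8-bit array indexed ``(slice, axial_row,
lateral_col)`` together with its voxel geometry.  On disk a volume is a
multi-page grayscale TIFF (one page per B-scan) plus a JSON geometry sidecar;
training manifests are plain CSV.  The proprietary device container is out of
scope — volumes enter the pipeline already converted to plain arrays.

Orientation convention: column 0 is the temporal side for right eyes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "VoxelGeometry",
    "OCTVolume",
    "write_volume",
    "read_volume",
    "split_cases",
    "write_manifest",
    "read_manifest",
    "MANIFEST_COLUMNS",
]

#: columns of a training manifest, in canonical order
MANIFEST_COLUMNS = [
    "case_id",
    "split",
    "slice_index",
    "condition",
    "augmentation_tag",
    "sampling_weight",
    "pre_path",
    "post_path",
]

SPLITS = ("train", "validation", "test")
AUGMENTATION_TAGS = ("orig", "flip", "rot4", "rot8", "shift_t", "shift_n")


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical pitch of a volume in micrometres per voxel step.

    ``slice_pitch`` separates adjacent B-scans, ``axial_pitch`` adjacent rows
    within a B-scan (depth), ``lateral_pitch`` adjacent A-scan columns.
    """

    slice_pitch: float
    axial_pitch: float
    lateral_pitch: float

    def __post_init__(self) -> None:
        if not (self.slice_pitch > 0 and self.axial_pitch > 0 and self.lateral_pitch > 0):
            raise ValueError("all voxel pitches must be positive")

    @classmethod
    def default(
        cls,
        n_slices: int = 256,
        n_lateral: int = 512,
        scan_width_um: float = 6000.0,
        axial_pitch_um: float = 2.6,
    ) -> "VoxelGeometry":
        """Geometry of a 6 x 6 mm^2 macular cube sampled 256 x 992 x 512."""
        return cls(
            slice_pitch=scan_width_um / n_slices,
            axial_pitch=axial_pitch_um,
            lateral_pitch=scan_width_um / n_lateral,
        )

    def to_dict(self) -> dict:
        return {
            "slice_pitch": self.slice_pitch,
            "axial_pitch": self.axial_pitch,
            "lateral_pitch": self.lateral_pitch,
        }


@dataclass
class OCTVolume:
    """An 8-bit OCT cube with its voxel geometry.

    ``data`` is indexed ``(slice, axial_row, lateral_col)``; values in [0, 255].
    """

    data: np.ndarray
    geometry: VoxelGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if self.data.dtype != np.uint8:
            if self.data.min() < 0 or self.data.max() > 255:
                raise ValueError("volume intensities must lie in [0, 255]")
            self.data = self.data.astype(np.uint8)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_axial(self) -> int:
        return self.data.shape[1]

    @property
    def n_lateral(self) -> int:
        return self.data.shape[2]

    def slice(self, index: int) -> np.ndarray:
        """Return B-scan ``index`` as a 2-D (axial, lateral) uint8 array."""
        return self.data[index]


class CorruptVolumeError(RuntimeError):
    """Raised when a volume on disk disagrees with (or lacks) its sidecar."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(volume: OCTVolume, path: str | Path) -> Path:
    """Write a volume as a multi-page TIFF plus JSON geometry sidecar.

    The round trip through :func:`read_volume` is bit-exact.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.data, photometric="minisblack")
    meta = {
        "n_slices": volume.n_slices,
        "n_axial": volume.n_axial,
        "n_lateral": volume.n_lateral,
        **volume.geometry.to_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_volume(path: str | Path) -> OCTVolume:
    """Read a TIFF volume written by :func:`write_volume`.

    A missing sidecar or a shape mismatch raises :class:`CorruptVolumeError`
    rather than silently assuming defaults.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise CorruptVolumeError(f"missing geometry sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    expect = (meta["n_slices"], meta["n_axial"], meta["n_lateral"])
    if tuple(data.shape) != expect:
        raise CorruptVolumeError(
            f"volume shape {data.shape} does not match sidecar {expect}"
        )
    geometry = VoxelGeometry(
        slice_pitch=meta["slice_pitch"],
        axial_pitch=meta["axial_pitch"],
        lateral_pitch=meta["lateral_pitch"],
    )
    return OCTVolume(data=data, geometry=geometry)


def split_cases(
    case_ids,
    ratios: tuple[int, int, int] = (4, 1, 1),
    seed: int = 0,
) -> pd.DataFrame:
    """Randomly partition cases into train/validation/test at the given ratios.

    Allocation is by non-repeating random assignment: floor counts per split,
    remainders go to training.  150 cases at 4:1:1 give 100/25/25.

    Returns a manifest skeleton DataFrame with ``case_id`` and ``split``.
    """
    case_ids = list(case_ids)
    if not case_ids:
        raise ValueError("no cases to split")
    if len(set(case_ids)) != len(case_ids):
        raise ValueError("case ids must be unique")
    total = sum(ratios)
    n = len(case_ids)
    n_val = (n * ratios[1]) // total
    n_test = (n * ratios[2]) // total
    n_train = n - n_val - n_test  # remainders accrue to training
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    labels[order[:n_train]] = "train"
    labels[order[n_train : n_train + n_val]] = "validation"
    labels[order[n_train + n_val :]] = "test"
    return pd.DataFrame({"case_id": case_ids, "split": labels})


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    """Write a training manifest as CSV (canonical column order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in MANIFEST_COLUMNS if c in manifest.columns]
    cols += [c for c in manifest.columns if c not in cols]
    manifest[cols].to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    _validate_manifest(df)
    return df


def _validate_manifest(df: pd.DataFrame) -> None:
    missing = [c for c in ("case_id", "split", "slice_index", "condition") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    bad = set(df["split"]) - set(SPLITS)
    if bad:
        raise ValueError(f"unknown split labels {sorted(bad)}")
    if "sampling_weight" in df.columns:
        w = df["sampling_weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("sampling weights must be finite and positive")
    key = df[["case_id", "slice_index", "augmentation_tag"]].apply(tuple, axis=1)
    if key.duplicated().any():
        raise ValueError("duplicate (case, slice, augmentation) rows in manifest")
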