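"""Volume I/O, subject manifests, and grid resampling.

All volumes are plain 3-D scalar arrays with an (x, y, z) axis order;
z is the slice axis.  NIfTI-1/2 is the on-disk format for volumes and
masks; manifests are YAML (JSON is a YAML subset and accepted too).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml
from scipy import ndimage


class VolumeError(ValueError):
    """Raised for unreadable, malformed, or geometrically invalid volumes."""


@dataclass
class VolumeImage:
    """A 3-D scalar volume with voxel geometry.

    Parameters
    ----------
    data : ndarray
        3-D array, axis order (x, y, z); z is the slice axis.
    voxel_size : tuple of float
        Voxel edge lengths in mm, strictly positive.
    orientation : str
        Axis-order code (e.g. ``"RAS"``).
    units : str
        Free-text tag describing the value units (e.g. ``"a.u."``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation: str = "RAS"
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise VolumeError(f"volume must be 3-D, got {self.data.ndim}-D")
        if any(d < 1 for d in self.data.shape):
            raise VolumeError(f"degenerate volume shape {self.data.shape}")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise VolumeError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "VolumeImage") -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_size, other.voxel_size)

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """Copy of this volume carrying new voxel data on the same grid."""
        return VolumeImage(np.asarray(data), self.voxel_size, self.orientation, self.units)


def read_volume(path: str | os.PathLike) -> VolumeImage:
    """Read a NIfTI-1/2 volume from ``path``.

    Raises
    ------
    VolumeError
        If the file is missing, unreadable, or not a 3-D payload.
        4-D files must be split explicitly before loading.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise VolumeError(f"unreadable volume: {path} ({exc})") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(f"expected 3-D payload in {path}, got shape {data.shape}; split 4-D series explicitly")
    zooms = img.header.get_zooms()[:3]
    try:
        orientation = "".join(nib.aff2axcodes(img.affine))
    except Exception:
        orientation = "RAS"
    return VolumeImage(np.asarray(data, dtype=np.float64), tuple(float(z) for z in zooms), orientation)


def write_volume(path: str | os.PathLike, volume: VolumeImage) -> None:
    """Write a volume to NIfTI with a diagonal affine from its voxel size."""
    affine = np.diag(list(volume.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), affine)
    img.header.set_zooms(volume.voxel_size)
    nib.save(img, str(path))


@dataclass
class SubjectManifest:
    """Paths and per-subject parameters for one pipeline run."""

    subject_id: str
    tr_series_paths: list[str]
    tr_values_ms: list[float]
    mask_paths: dict[str, str] = field(default_factory=dict)
    cbf_path: str | None = None
    anatomical_path: str | None = None
    hct: float | None = None
    age_years: float | None = None
    sex: int | None = None

    REQUIRED_MASKS = ("brain", "blood", "phantom_1", "phantom_2", "phantom_3", "phantom_4", "phantom_5")

    def __post_init__(self) -> None:
        self.tr_values_ms = [float(t) for t in self.tr_values_ms]
        if len(self.tr_series_paths) != len(self.tr_values_ms):
            raise ValueError(
                f"subject {self.subject_id!r}: {len(self.tr_series_paths)} series paths "
                f"but {len(self.tr_values_ms)} TR values"
            )
        if any(t <= 0 for t in self.tr_values_ms):
            raise ValueError(f"subject {self.subject_id!r}: TR values must be positive")
        if any(b <= a for a, b in zip(self.tr_values_ms, self.tr_values_ms[1:])):
            raise ValueError(f"subject {self.subject_id!r}: TR values must be strictly increasing")
        if self.hct is not None:
            self.hct = float(self.hct)
            if not 0.0 < self.hct < 1.0:
                raise ValueError(f"subject {self.subject_id!r}: hct must be a fraction in (0, 1), got {self.hct}")
        if self.age_years is not None and float(self.age_years) <= 0:
            raise ValueError(f"subject {self.subject_id!r}: age_years must be positive")


def _manifest_from_dict(entry: Mapping) -> SubjectManifest:
    known = {
        "subject_id",
        "tr_series_paths",
        "tr_values_ms",
        "mask_paths",
        "cbf_path",
        "anatomical_path",
        "hct",
        "age_years",
        "sex",
    }
    missing = {"subject_id", "tr_series_paths", "tr_values_ms"} - set(entry)
    if missing:
        raise ValueError(f"manifest entry missing required keys: {sorted(missing)}")
    return SubjectManifest(**{k: v for k, v in entry.items() if k in known})


def load_manifest(path: str | os.PathLike) -> SubjectManifest:
    """Load and validate a single-subject manifest (YAML or JSON)."""
    with open(path) as fh:
        entry = yaml.safe_load(fh)
    if not isinstance(entry, Mapping):
        raise ValueError(f"manifest {path} is not a mapping")
    if "subjects" in entry:
        raise ValueError(f"{path} is a cohort manifest; use load_cohort_manifest")
    return _manifest_from_dict(entry)


def load_cohort_manifest(path: str | os.PathLike) -> list[SubjectManifest]:
    """Load a cohort manifest: mapping with a ``subjects`` list."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "subjects" not in doc:
        raise ValueError(f"cohort manifest {path} must contain a 'subjects' list")
    return [_manifest_from_dict(e) for e in doc["subjects"]]


def save_cohort_manifest(path: str | os.PathLike, subjects: Sequence[SubjectManifest]) -> None:
    doc = {"subjects": []}
    for s in subjects:
        entry = {
            "subject_id": s.subject_id,
            "tr_series_paths": list(s.tr_series_paths),
            "tr_values_ms": list(s.tr_values_ms),
            "mask_paths": dict(s.mask_paths),
        }
        for key in ("cbf_path", "anatomical_path", "hct", "age_years", "sex"):
            value = getattr(s, key)
            if value is not None:
                entry[key] = value
        doc["subjects"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def resample_to(reference: VolumeImage, moving: VolumeImage, mode: str = "linear") -> VolumeImage:
    """Resample ``moving`` onto the voxel grid of ``reference``.

    Both volumes are assumed co-registered with a shared field-of-view
    corner at voxel (0, 0, 0).  ``mode`` is ``"nearest"`` (order-0, label
    safe) or ``"linear"`` (order-1 intensities).  Linear interpolation of
    a multi-label volume is refused because it invents labels.
    """
    if mode not in ("nearest", "linear"):
        raise ValueError(f"mode must be 'nearest' or 'linear', got {mode!r}")
    data = np.asarray(moving.data)
    if mode == "linear":
        is_integral = np.issubdtype(data.dtype, np.integer) or np.all(data == np.round(data))
        if is_integral and np.unique(data).size > 2:
            raise ValueError("labels require nearest interpolation")
    # reference voxel centers expressed in moving-volume voxel coordinates
    coords = np.meshgrid(
        *[np.arange(n, dtype=np.float64) for n in reference.shape], indexing="ij", copy=False
    )
    mapped = [
        (c + 0.5) * reference.voxel_size[ax] / moving.voxel_size[ax] - 0.5 for ax, c in enumerate(coords)
    ]
    order = 0 if mode == "nearest" else 1
    out = ndimage.map_coordinates(
        np.asarray(data, dtype=np.float64), np.stack(mapped), order=order, mode="nearest"
    )
    return VolumeImage(out, reference.voxel_size, reference.orientation, moving.units)


def write_table(path: str | os.PathLike, rows: Sequence[Mapping], columns: Sequence[str] | None = None) -> None:
    """Write a list of dict rows as headered CSV."""
    import pandas as pd

    df = pd.DataFrame(list(rows))
    if columns:
        df = df[list(columns)]
    df.to_csv(path, index=False)


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML/JSON run configuration file."""
    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)
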