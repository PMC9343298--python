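"""NIfTI volume I/O and train-set-anchored intensity normalization.

All volumes in one analysis live on a single template grid; mismatched
grids are an error here, never silently resampled (spatial normalization
belongs to upstream preprocessing, which this package does not do).

Normalization follows the training protocol: the global minimum and
maximum over *all voxels of all training volumes* of one index map the
training data onto [0, 1]; test volumes use the same parameters and are
clipped into [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateRangeError, ValidationError

#: identity affine scaled to 2 mm isotropic voxels
AFFINE_2MM = np.diag([2.0, 2.0, 2.0, 1.0])


@dataclass
class IndexVolume:
    """One subject's 3D scalar field for one MR index."""

    data: np.ndarray
    index_name: str = ""
    subject_id: str = ""

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return tuple(self.data.shape)


def read_volume(path: str | Path, index_name: str = "",
                subject_id: str = "") -> IndexVolume:
    """Load a 3D NIfTI volume; 4D images or non-finite voxels are errors."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise ValidationError(f"{path.name}: expected a 3D volume, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path.name}: volume contains NaN or infinite voxels")
    return IndexVolume(data=data, index_name=index_name, subject_id=subject_id)


def write_volume(data: np.ndarray, path: str | Path,
                 affine: np.ndarray = AFFINE_2MM) -> None:
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got shape {data.shape}")
    nib.save(nib.Nifti1Image(data, affine), str(path))


@dataclass
class NormParams:
    """Global training-set intensity range for one index."""

    vmin: float
    vmax: float

    def __post_init__(self) -> None:
        if not self.vmax > self.vmin:
            raise DegenerateRangeError(f"vmax ({self.vmax}) must exceed vmin ({self.vmin})")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"vmin": self.vmin, "vmax": self.vmax}))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormParams":
        d = json.loads(Path(path).read_text())
        return cls(vmin=d["vmin"], vmax=d["vmax"])


def _stack(volumes) -> np.ndarray:
    if isinstance(volumes, np.ndarray):
        arrs = [volumes] if volumes.ndim == 3 else list(volumes)
    else:
        arrs = [v.data if isinstance(v, IndexVolume) else np.asarray(v)
                for v in volumes]
    if not arrs:
        raise ValidationError("need at least one volume")
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValidationError(f"grid mismatch: {a.shape} vs {shape}")
        if not np.all(np.isfinite(a)):
            raise ValidationError("volume contains NaN or infinite voxels")
    return np.stack(arrs)


def minmax_fit(training_volumes) -> NormParams:
    """Global (vmin, vmax) over every voxel of every training volume."""
    stacked = _stack(training_volumes)
    vmin, vmax = float(stacked.min()), float(stacked.max())
    if vmax <= vmin:
        raise DegenerateRangeError("training volumes are constant; the intensity "
                                   "range is degenerate")
    return NormParams(vmin=vmin, vmax=vmax)


def minmax_apply(volume, params: NormParams):
    """(x - vmin)/(vmax - vmin), clipped to [0, 1]."""
    data = volume.data if isinstance(volume, IndexVolume) else np.asarray(volume)
    scaled = (data - params.vmin) / (params.vmax - params.vmin)
    scaled = np.clip(scaled, 0.0, 1.0).astype(np.float32)
    if isinstance(volume, IndexVolume):
        return IndexVolume(scaled, volume.index_name, volume.subject_id)
    return scaled


class MinMaxVolumeScaler(TransformerMixin, BaseEstimator):
    """Sklearn-style wrapper: fit the global range on the training split,
    map volumes into [0, 1] with clipping at transform time."""

    def fit(self, X, y=None):
        params = minmax_fit(X)
        self.vmin_, self.vmax_ = params.vmin, params.vmax
        return self

    def transform(self, X):
        params = NormParams(self.vmin_, self.vmax_)
        if isinstance(X, np.ndarray):
            return minmax_apply(X, params) if X.ndim == 3 else np.stack(
                [minmax_apply(v, params) for v in X])
        return [minmax_apply(v, params) for v in X]

    @property
    def params_(self) -> NormParams:
        return NormParams(self.vmin_, self.vmax_)
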