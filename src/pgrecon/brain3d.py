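"""Synthetic 3D brain phantom: ellipsoid volume with Gaussian activations.

The brain is idealised as the ellipsoid ``x^2/a^2 + y^2/b^2 + z^2/c^2 <= 1``
inside the cube ``[-1, 1]^3``.  Functional activity is modelled as localised
isotropic Gaussian blobs ``amplitude * exp(-alpha * |x - x0|^2)`` added to a
low uniform tissue background; the volume is clipped to ``[0, 1]`` and is
exactly zero outside the ellipsoid.  Axial (fixed-z) slices feed the 2D
reconstruction network; slice-wise processing is the default 3D strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ActivationSpec",
    "BrainVolumeSpec",
    "BrainVolume",
    "ellipsoid_mask",
    "activation_field",
    "build_brain_volume",
    "axial_slices",
    "to_nifti",
    "from_nifti",
    "volume_coords",
]


@dataclass(frozen=True)
class ActivationSpec:
    """One activation blob: centre, spread ``alpha`` and peak amplitude."""

    center: tuple[float, float, float]
    alpha: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be strictly positive")
        if not (0.0 < self.amplitude <= 1.0):
            raise ValueError("amplitude must lie in (0, 1]")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass(frozen=True)
class BrainVolumeSpec:
    """Ellipsoid semi-axes, voxel grid shape and the activation list."""

    semi_axes: tuple[float, float, float] = (0.9, 0.7, 0.8)
    shape: tuple[int, int, int] = (48, 48, 48)
    activations: tuple[ActivationSpec, ...] = ()
    background: float = 0.1

    def __post_init__(self) -> None:
        if any(not (0.0 < s <= 1.0) for s in self.semi_axes):
            raise ValueError("semi-axes must lie in (0, 1]")
        if any(n < 8 for n in self.shape):
            raise ValueError("volume grid must be at least 8 voxels per axis")
        if not (0.0 <= self.background <= 0.2):
            raise ValueError("background must lie in [0, 0.2]")
        object.__setattr__(self, "activations", tuple(self.activations))

    def contains(self, point: Sequence[float]) -> bool:
        a, b, c = self.semi_axes
        x, y, z = point
        return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0


@dataclass(frozen=True)
class BrainVolume:
    """Sampled volume, its ellipsoid mask and the generating spec."""

    values: np.ndarray
    mask: np.ndarray
    spec: BrainVolumeSpec


def volume_coords(shape: tuple[int, int, int]):
    """Per-axis voxel-node coordinates over ``[-1, 1]^3`` (endpoints included)."""
    return tuple(np.linspace(-1.0, 1.0, n) for n in shape)


def _mesh3(shape):
    x, y, z = volume_coords(shape)
    return np.meshgrid(x, y, z, indexing="ij")


def ellipsoid_mask(spec: BrainVolumeSpec) -> np.ndarray:
    """True exactly where ``x^2/a^2 + y^2/b^2 + z^2/c^2 <= 1``."""
    a, b, c = spec.semi_axes
    X, Y, Z = _mesh3(spec.shape)
    return (X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2 <= 1.0


def activation_field(
    act: ActivationSpec, shape: tuple[int, int, int]
) -> np.ndarray:
    """``amplitude * exp(-alpha * ((x-x0)^2 + (y-y0)^2 + (z-z0)^2))`` on the
    voxel grid."""
    X, Y, Z = _mesh3(shape)
    x0, y0, z0 = act.center
    r2 = (X - x0) ** 2 + (Y - y0) ** 2 + (Z - z0) ** 2
    return act.amplitude * np.exp(-act.alpha * r2)


def build_brain_volume(spec: BrainVolumeSpec) -> BrainVolume:
    """Background-filled ellipsoid plus superposed activations, clipped to
    ``[0, 1]`` and exactly zero outside the mask.

    Activation centres must satisfy the ellipsoid membership condition.
    """
    for act in spec.activations:
        if not spec.contains(act.center):
            raise ValueError(f"activation center {act.center} outside ellipsoid")
    mask = ellipsoid_mask(spec)
    values = np.full(spec.shape, float(spec.background))
    for act in spec.activations:
        values += activation_field(act, spec.shape)
    values = np.clip(values, 0.0, 1.0)
    values *= mask
    return BrainVolume(values, mask, spec)


def axial_slices(
    volume: np.ndarray, indices: Optional[Sequence[int]] = None
) -> list[tuple[int, np.ndarray]]:
    """Fixed-z planes of a volume as ``(z_index, 2D array)`` pairs."""
    nz = volume.shape[2]
    if indices is None:
        indices = range(nz)
    out = []
    for k in indices:
        if not (0 <= k < nz):
            raise IndexError(f"slice index {k} out of range [0, {nz})")
        out.append((int(k), volume[:, :, k]))
    return out


def to_nifti(volume: np.ndarray, path) -> None:
    """Write a volume sampled on ``[-1, 1]^3`` as NIfTI with a diagonal
    voxel-size affine anchored at ``(-1, -1, -1)``."""
    import nibabel as nib

    shape = volume.shape
    voxdims = [2.0 / (n - 1) for n in shape]
    affine = np.diag(voxdims + [1.0])
    affine[:3, 3] = -1.0
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


def from_nifti(path) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
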