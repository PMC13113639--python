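"""Parametric 2D scalar-field phantoms on a regular grid.

Clean biomedical image intensity is modelled as a continuous physical field
``u(x) = f(x; theta)`` sampled on a regular node grid over the square domain
``[-1, 1]^2``.  Three functional families ("modalities" in the loose sense of
field character, not scanner hardware) are provided:

* **gaussian** — smooth isotropic blobs ``exp(-alpha * |x - x0|^2)``
  emulating localised tissue activation or metabolic uptake;
* **wave** — a direction-projected sinusoid emulating oscillatory imaging
  patterns;
* **step** — uniformly quantised radial patterns (Gaussian- or square-based)
  emulating abrupt tissue transitions and layered structures.

All fields are kept on the ``[0, 1]`` intensity scale so that downstream
quality metrics (PSNR in particular) can use a fixed data range of 1.0.
Coordinates are sampled at grid *nodes*: both domain endpoints are included
and the spacing is ``extent_length / (n - 1)``.

Array convention: ``values[i, j] = u(x_i, y_j)`` (``indexing="ij"``),
shape ``(n_x, n_y)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "DEFAULT_EXTENT",
    "MIN_GRID_SIDE",
    "GridSpec",
    "FieldSpec",
    "Field",
    "make_grid",
    "gaussian_field",
    "wave_field",
    "step_field",
    "normalize_unit_range",
    "evaluate_field_spec",
    "save_png_preview",
]

DEFAULT_EXTENT: tuple[tuple[float, float], tuple[float, float]] = (
    (-1.0, 1.0),
    (-1.0, 1.0),
)

# Coarser grids leave no room for the 5-point Laplacian interior plus the
# 11-pixel SSIM window, so they are rejected outright.
MIN_GRID_SIDE = 8

_MODALITIES = ("gaussian", "wave", "step_gaussian", "step_square")


@dataclass(frozen=True)
class GridSpec:
    """Regular node grid over a rectangular domain (default ``[-1, 1]^2``)."""

    n_x: int = 64
    n_y: int = 64
    extent: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_EXTENT

    def __post_init__(self) -> None:
        if self.n_x < MIN_GRID_SIDE or self.n_y < MIN_GRID_SIDE:
            raise ValueError(
                f"grid must be at least {MIN_GRID_SIDE} nodes per axis, "
                f"got {self.n_x}x{self.n_y}"
            )
        for lo, hi in self.extent:
            if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
                raise ValueError(f"invalid extent interval ({lo}, {hi})")

    @property
    def spacing(self) -> tuple[float, float]:
        (x0, x1), (y0, y1) = self.extent
        return (x1 - x0) / (self.n_x - 1), (y1 - y0) / (self.n_y - 1)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_x, self.n_y)


@dataclass(frozen=True)
class FieldSpec:
    """Parametric description of a clean field: modality plus parameters.

    ``params`` holds the modality-specific physical parameters, e.g.
    ``center``/``alpha`` for Gaussian blobs, ``freq``/``phase`` for waves,
    ``levels``/``pattern`` for step fields.
    """

    modality: str
    params: dict
    normalization: str = "unit_range"

    def __post_init__(self) -> None:
        if self.modality not in _MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.normalization not in ("unit_range", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass(frozen=True)
class Field:
    """A sampled scalar field together with its grid and generating spec."""

    values: np.ndarray
    grid: GridSpec
    spec: Optional[FieldSpec] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.shape:
            raise ValueError(
                f"values shape {v.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("field values must be finite everywhere")
        object.__setattr__(self, "values", v)


def make_grid(spec: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis node coordinates; first/last entries are the domain endpoints."""
    (x0, x1), (y0, y1) = spec.extent
    x = np.linspace(x0, x1, spec.n_x)
    y = np.linspace(y0, y1, spec.n_y)
    return x, y


def _mesh(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    x, y = make_grid(grid)
    return np.meshgrid(x, y, indexing="ij")


def _check_center_inside(grid: GridSpec, center: tuple[float, float]) -> None:
    (x0, x1), (y0, y1) = grid.extent
    cx, cy = center
    if not (x0 <= cx <= x1 and y0 <= cy <= y1):
        raise ValueError(f"center {center} lies outside the domain extent")


def gaussian_field(
    grid: GridSpec,
    center: tuple[float, float] = (0.0, 0.0),
    alpha: float = 25.0,
    normalization: str = "unit_range",
) -> Field:
    """Isotropic Gaussian blob ``exp(-alpha * ((x-x0)^2 + (y-y0)^2))``.

    ``alpha`` controls the spatial spread (larger = tighter blob); it must be
    strictly positive.  The peak value before normalisation is exactly 1 at
    the blob centre.
    """
    if alpha <= 0:
        raise ValueError("alpha must be strictly positive")
    _check_center_inside(grid, center)
    X, Y = _mesh(grid)
    values = np.exp(-alpha * ((X - center[0]) ** 2 + (Y - center[1]) ** 2))
    spec = FieldSpec(
        "gaussian",
        {"center": tuple(center), "alpha": float(alpha)},
        normalization,
    )
    f = Field(values, grid, spec)
    return normalize_unit_range(f) if normalization == "unit_range" else f


def wave_field(
    grid: GridSpec,
    freq: tuple[float, float] = (1.5, 0.0),
    phase: float = 0.0,
    normalization: str = "none",
) -> Field:
    """Direction-projected sinusoid ``0.5 * (1 + sin(2*pi*(fx*x + fy*y) + phase))``.

    Values lie in ``[0, 1]`` by construction, so normalisation defaults to
    ``none`` (keeping closed-form point values exact).  A field with both
    frequencies zero is a degenerate constant and is rejected.
    """
    fx, fy = freq
    if fx == 0 and fy == 0:
        raise ValueError("at least one frequency must be nonzero")
    X, Y = _mesh(grid)
    values = 0.5 * (1.0 + np.sin(2.0 * np.pi * (fx * X + fy * Y) + phase))
    spec = FieldSpec(
        "wave", {"freq": (float(fx), float(fy)), "phase": float(phase)}, normalization
    )
    f = Field(values, grid, spec)
    return normalize_unit_range(f) if normalization == "unit_range" else f


def _quantize_unit(values: np.ndarray, levels: int) -> np.ndarray:
    # Uniform quantiser onto {0, 1/(L-1), ..., 1}; idempotent on its own output.
    return np.round(values * (levels - 1)) / (levels - 1)


def step_field(
    grid: GridSpec,
    pattern: str = "gaussian",
    levels: int = 5,
    center: tuple[float, float] = (0.0, 0.0),
    alpha: float = 8.0,
    base: Optional[Field] = None,
) -> Field:
    """Step-quantised field with exactly ``<= levels`` intensity plateaus.

    ``pattern="gaussian"`` quantises a radial Gaussian (concentric rings);
    ``pattern="square"`` quantises the Chebyshev distance to the centre
    (concentric squares).  Alternatively an explicit ``base`` field is
    quantised.  Plateau values sit uniformly on ``{0, 1/(L-1), ..., 1}``.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if base is not None:
        v = base.values
        lo, hi = v.min(), v.max()
        if hi <= lo:
            raise ValueError("cannot quantize a constant base field")
        v = (v - lo) / (hi - lo)
        pattern = "base"
    elif pattern == "gaussian":
        g = gaussian_field(grid, center=center, alpha=alpha)
        v = g.values
    elif pattern == "square":
        _check_center_inside(grid, center)
        X, Y = _mesh(grid)
        cheb = np.maximum(np.abs(X - center[0]), np.abs(Y - center[1]))
        v = 1.0 - cheb / cheb.max()
    else:
        raise ValueError(f"unknown step pattern {pattern!r}")
    q = _quantize_unit(v, levels)
    modality = "step_square" if pattern == "square" else "step_gaussian"
    spec = FieldSpec(
        modality,
        {
            "pattern": pattern,
            "levels": int(levels),
            "center": tuple(center),
            "alpha": float(alpha),
        },
        "unit_range",
    )
    return Field(q, grid, spec)


def normalize_unit_range(f: Field) -> Field:
    """Affine rescale to ``min 0, max 1``; rejects constant fields."""
    lo = float(f.values.min())
    hi = float(f.values.max())
    if hi <= lo:
        raise ValueError("cannot unit-range normalize a constant field")
    if lo == 0.0 and hi == 1.0:
        return f
    values = (f.values - lo) / (hi - lo)
    spec = replace(f.spec, normalization="unit_range") if f.spec else None
    return Field(values, f.grid, spec)


def evaluate_field_spec(grid: GridSpec, spec: FieldSpec) -> Field:
    """Re-materialise a field from its parametric spec (used for serialization
    round trips and for inclusion interiors)."""
    p = spec.params
    if spec.modality == "gaussian":
        return gaussian_field(
            grid,
            center=tuple(p["center"]),
            alpha=p["alpha"],
            normalization=spec.normalization,
        )
    if spec.modality == "wave":
        return wave_field(
            grid,
            freq=tuple(p["freq"]),
            phase=p.get("phase", 0.0),
            normalization=spec.normalization,
        )
    if spec.modality in ("step_gaussian", "step_square"):
        return step_field(
            grid,
            pattern=p.get("pattern", "gaussian"),
            levels=p.get("levels", 5),
            center=tuple(p.get("center", (0.0, 0.0))),
            alpha=p.get("alpha", 8.0),
        )
    raise ValueError(f"unknown modality {spec.modality!r}")


def save_png_preview(f: Field, path) -> None:
    """8-bit grayscale preview (visual inspection only; metrics always run on
    the float arrays)."""
    from PIL import Image

    v = f.values
    lo, hi = v.min(), v.max()
    scaled = np.zeros_like(v) if hi <= lo else (v - lo) / (hi - lo)
    # transpose so x runs left-right, y bottom-up in the usual image sense
    img = np.flipud((scaled.T * 255.0).round().astype(np.uint8))
    Image.fromarray(img, mode="L").save(path)
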