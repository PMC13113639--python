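"""Geometric inclusions and heterogeneous field composition.

Biological tissue is heterogeneous: lesions and anomalies appear as
sub-regions (inclusions) whose intensity follows a distinct parametric field
while the surrounding tissue is quiescent.  A composed field equals the
inclusion's interior field inside the inclusion and the background (default
zero) everywhere else.  Multiple inclusions may be superimposed; overlaps
resolve by pointwise maximum so intensities never exceed the interior fields'
own range.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

from .fields import Field, FieldSpec, GridSpec, evaluate_field_spec, make_grid

__all__ = [
    "InclusionSpec",
    "inclusion_mask",
    "compose_inclusions",
    "irregular_inclusions",
    "inclusion_to_yaml",
    "inclusion_from_yaml",
]

_SHAPES = ("circle", "ellipse", "rectangle")


@dataclass(frozen=True)
class InclusionSpec:
    """One inclusion: shape, placement, size and its interior field.

    ``size`` is the radius for a circle, the semi-axes ``(r_a, r_b)`` for an
    ellipse and the half-widths ``(w, h)`` for a rectangle, all in domain
    units.  ``angle`` rotates the shape counter-clockwise about its centre.
    ``interior_field=None`` defaults to a Gaussian blob centred on the
    inclusion whose spread puts ``exp(-2)`` at the inclusion boundary.
    """

    shape: str
    center: tuple[float, float]
    size: tuple[float, ...]
    angle: float = 0.0
    interior_field: Optional[FieldSpec] = None

    def __post_init__(self) -> None:
        if self.shape not in _SHAPES:
            raise ValueError(f"unknown inclusion shape {self.shape!r}")
        size = tuple(float(s) for s in np.atleast_1d(self.size))
        n_expected = 1 if self.shape == "circle" else 2
        if len(size) != n_expected:
            raise ValueError(
                f"{self.shape} inclusion needs {n_expected} size parameter(s)"
            )
        if any(s <= 0 for s in size):
            raise ValueError("all size parameters must be strictly positive")
        object.__setattr__(self, "size", size)
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    def default_interior(self) -> FieldSpec:
        r_eff = float(np.mean(self.size))
        return FieldSpec(
            "gaussian",
            {"center": self.center, "alpha": 2.0 / r_eff**2},
            "none",
        )


def _rotated_offsets(grid: GridSpec, spec: InclusionSpec):
    x, y = make_grid(grid)
    X, Y = np.meshgrid(x, y, indexing="ij")
    dx = X - spec.center[0]
    dy = Y - spec.center[1]
    if spec.angle:
        c, s = np.cos(spec.angle), np.sin(spec.angle)
        dx, dy = c * dx + s * dy, -s * dx + c * dy
    return dx, dy


def inclusion_mask(grid: GridSpec, spec: InclusionSpec) -> np.ndarray:
    """Boolean grid, true exactly where the node lies inside the (rotated)
    shape; boundary points (equality) count as inside."""
    dx, dy = _rotated_offsets(grid, spec)
    if spec.shape == "circle":
        (r,) = spec.size
        return dx**2 + dy**2 <= r**2
    if spec.shape == "ellipse":
        ra, rb = spec.size
        return (dx / ra) ** 2 + (dy / rb) ** 2 <= 1.0
    w, h = spec.size
    return (np.abs(dx) <= w) & (np.abs(dy) <= h)


def compose_inclusions(
    grid: GridSpec,
    specs: Sequence[InclusionSpec],
    background: Optional[Field] = None,
) -> Field:
    """Heterogeneous field: interior field inside each inclusion, background
    outside all of them (bit-identical), overlaps resolved by maximum.

    The result is affinely renormalised to ``[0, 1]`` only if it strays
    outside that range, so a zero background stays exactly zero.
    """
    if len(specs) == 0:
        raise ValueError("specs must be non-empty")
    out = (
        np.zeros(grid.shape)
        if background is None
        else np.array(background.values, dtype=float)
    )
    interior = np.full(grid.shape, -np.inf)
    any_mask = np.zeros(grid.shape, dtype=bool)
    for spec in specs:
        mask = inclusion_mask(grid, spec)
        fspec = spec.interior_field or spec.default_interior()
        vals = evaluate_field_spec(grid, fspec).values
        interior = np.where(mask, np.maximum(interior, vals), interior)
        any_mask |= mask
    out = np.where(any_mask, interior, out)
    lo, hi = out.min(), out.max()
    if lo < 0.0 or hi > 1.0:
        out = (out - lo) / (hi - lo)
    return Field(out, grid)


def irregular_inclusions(
    center: tuple[float, float],
    rng: np.random.Generator,
    n_lobes: tuple[int, int] = (3, 5),
    scale: float = 0.22,
) -> list[InclusionSpec]:
    """An "irregular" region as the union of 3-5 random overlapping ellipses
    scattered around ``center`` (no canonical definition exists; this is the
    package's seeded construction)."""
    k = int(rng.integers(n_lobes[0], n_lobes[1] + 1))
    specs = []
    for _ in range(k):
        cx = center[0] + rng.uniform(-0.5, 0.5) * scale
        cy = center[1] + rng.uniform(-0.5, 0.5) * scale
        ra = rng.uniform(0.4, 1.0) * scale
        rb = rng.uniform(0.4, 1.0) * scale
        angle = rng.uniform(0.0, np.pi)
        specs.append(InclusionSpec("ellipse", (cx, cy), (ra, rb), angle))
    return specs


def _spec_to_dict(spec: InclusionSpec) -> dict:
    d = asdict(spec)
    if spec.interior_field is not None:
        d["interior_field"] = {
            "modality": spec.interior_field.modality,
            "params": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in spec.interior_field.params.items()
            },
            "normalization": spec.interior_field.normalization,
        }
    d["center"] = list(spec.center)
    d["size"] = list(spec.size)
    return d


def inclusion_to_yaml(specs: Sequence[InclusionSpec]) -> str:
    """Human-readable config block for a list of inclusions."""
    return yaml.safe_dump([_spec_to_dict(s) for s in specs], sort_keys=False)


def inclusion_from_yaml(text: str) -> list[InclusionSpec]:
    out = []
    for d in yaml.safe_load(text):
        fs = None
        if d.get("interior_field"):
            fd = d["interior_field"]
            params = {
                k: tuple(v) if isinstance(v, list) else v
                for k, v in fd["params"].items()
            }
            fs = FieldSpec(fd["modality"], params, fd.get("normalization", "none"))
        out.append(
            InclusionSpec(
                d["shape"],
                tuple(d["center"]),
                tuple(d["size"]),
                d.get("angle", 0.0),
                fs,
            )
        )
    return out
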