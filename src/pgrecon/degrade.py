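"""Measurement degradation and seeded scenario datasets.

The measurement model is purely additive Gaussian noise,
``noisy(x) = clean(x) + eta(x)`` with ``eta ~ N(0, sigma^2)`` i.i.d. per
pixel.  Noisy inputs are *not* clipped by default: pure addition keeps the
closed-form calibration ``PSNR = 10*log10(1/sigma^2)`` exact, e.g. 26.02 dB
at the moderate level ``sigma = 0.05``.

Six evaluation scenarios are generated, each a seeded, paired
(noisy -> clean) dataset with disjoint train/val/test splits:

* ``inclusion_size`` — circular inclusions with radius swept over
  {0.10, 0.15, 0.20, 0.25};
* ``geometry``       — elliptical, rectangular and multiple-inclusion fields;
* ``modality``       — mixed Gaussian / wave / step fields;
* ``noise``          — mixed fields with sigma swept over {0.01, 0.05, 0.10};
* ``step3d``         — 5-level step-quantised Gaussian and square patterns
  (rendered as 3D surfaces downstream);
* ``brain3d``        — ellipsoid brain volumes with Gaussian activations,
  paired slice-wise.

One global seed expands into independent child streams (field geometry,
noise, splits) via ``numpy.random.SeedSequence.spawn``, so datasets are
bit-reproducible and the streams never alias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .brain3d import ActivationSpec, BrainVolumeSpec, build_brain_volume
from .fields import Field, GridSpec, gaussian_field, step_field, wave_field
from .geometry import InclusionSpec, compose_inclusions

__all__ = [
    "SCENARIOS",
    "NoiseSpec",
    "ScenarioConfig",
    "ScenarioDataset",
    "add_gaussian_noise",
    "generate_scenario",
    "save_archive",
    "load_archive",
]

SCENARIOS = (
    "inclusion_size",
    "geometry",
    "modality",
    "noise",
    "step3d",
    "brain3d",
)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive zero-mean Gaussian noise: standard deviation, seed, and an
    optional clip of the noisy output to [0, 1] (off by default)."""

    sigma: float
    seed: int = 0
    clip: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def add_gaussian_noise(field: Field | np.ndarray, spec: NoiseSpec):
    """``clean + N(0, sigma^2)`` i.i.d. per pixel; identical seeds give
    bit-identical output.  Accepts a Field or a bare array (any shape)."""
    values = field.values if isinstance(field, Field) else np.asarray(field, float)
    if spec.sigma == 0:
        noisy = values.copy()
    else:
        rng = np.random.default_rng(spec.seed)
        noisy = values + rng.normal(0.0, spec.sigma, size=values.shape)
    if spec.clip:
        noisy = np.clip(noisy, 0.0, 1.0)
    if isinstance(field, Field):
        return Field(noisy, field.grid, field.spec)
    return noisy


@dataclass(frozen=True)
class ScenarioConfig:
    """Dataset sizes and sweep settings for the six scenarios.

    2D scenarios use ``n_train/n_val/n_test`` image pairs on ``grid``;
    ``brain3d`` uses ``n_volumes`` volumes of shape ``brain_shape`` and pairs
    every axial slice whose ellipsoid-mask coverage is at least
    ``min_mask_coverage``.
    """

    n_train: int = 200
    n_val: int = 40
    n_test: int = 40
    grid: GridSpec = dc_field(default_factory=GridSpec)
    sigma: float = 0.05
    sigma_sweep: tuple[float, ...] = (0.01, 0.05, 0.10)
    radii: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25)
    n_volumes: tuple[int, int, int] = (12, 4, 4)
    brain_shape: tuple[int, int, int] = (48, 48, 48)
    min_mask_coverage: float = 0.05


@dataclass
class ScenarioDataset:
    """Paired (clean, noisy) images with per-pair metadata and disjoint
    train/val/test splits.  For ``brain3d`` the pairs are axial slices and
    ``volumes`` carries the underlying 3D cases for volumetric evaluation."""

    name: str
    clean: np.ndarray  # (N, H, W)
    noisy: np.ndarray  # (N, H, W)
    metadata: list[dict]
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    grid: GridSpec
    volumes: Optional[list[dict]] = None

    def __post_init__(self) -> None:
        n = self.clean.shape[0]
        all_idx = np.concatenate([self.train_idx, self.val_idx, self.test_idx])
        if len(set(all_idx.tolist())) != all_idx.size:
            raise ValueError("train/val/test splits must be disjoint")
        if all_idx.size and (all_idx.min() < 0 or all_idx.max() >= n):
            raise ValueError("split indices out of range")
        if self.noisy.shape != self.clean.shape or len(self.metadata) != n:
            raise ValueError("pairs and metadata must be aligned")

    def split(self, which: str) -> np.ndarray:
        return {"train": self.train_idx, "val": self.val_idx, "test": self.test_idx}[
            which
        ]


# ---------------------------------------------------------------------------
# per-scenario clean-field samplers (geometry stream only)
# ---------------------------------------------------------------------------


def _sample_inclusion_size(i, grid, rng, cfg):
    r = cfg.radii[i % len(cfg.radii)]
    center = tuple(rng.uniform(-0.35, 0.35, size=2))
    spec = InclusionSpec("circle", center, (r,))
    f = compose_inclusions(grid, [spec])
    return f, {"radius": r, "center": center}


def _sample_geometry(i, grid, rng, cfg):
    kind = ("ellipse", "rectangle", "multiple")[i % 3]
    if kind == "ellipse":
        specs = [
            InclusionSpec(
                "ellipse",
                tuple(rng.uniform(-0.3, 0.3, size=2)),
                (rng.uniform(0.12, 0.3), rng.uniform(0.12, 0.3)),
                angle=rng.uniform(0.0, np.pi),
            )
        ]
    elif kind == "rectangle":
        specs = [
            InclusionSpec(
                "rectangle",
                tuple(rng.uniform(-0.3, 0.3, size=2)),
                (rng.uniform(0.12, 0.3), rng.uniform(0.12, 0.3)),
                angle=rng.uniform(0.0, np.pi),
            )
        ]
    else:
        m = int(rng.integers(2, 4))
        specs = [
            InclusionSpec(
                "circle",
                tuple(rng.uniform(-0.45, 0.45, size=2)),
                (rng.uniform(0.08, 0.18),),
            )
            for _ in range(m)
        ]
    f = compose_inclusions(grid, specs)
    return f, {"geometry": kind, "n_inclusions": len(specs)}


def _sample_modality_field(i, grid, rng):
    kind = ("gaussian", "wave", "step")[i % 3]
    if kind == "gaussian":
        f = gaussian_field(
            grid,
            center=tuple(rng.uniform(-0.5, 0.5, size=2)),
            alpha=rng.uniform(4.0, 40.0),
        )
    elif kind == "wave":
        theta = rng.uniform(0.0, 2.0 * np.pi)
        mag = rng.uniform(0.5, 2.5)
        f = wave_field(
            grid,
            freq=(mag * np.cos(theta), mag * np.sin(theta)),
            phase=rng.uniform(0.0, 2.0 * np.pi),
        )
    else:
        pattern = "gaussian" if rng.uniform() < 0.5 else "square"
        f = step_field(
            grid,
            pattern=pattern,
            levels=5,
            center=tuple(rng.uniform(-0.25, 0.25, size=2)),
            alpha=rng.uniform(4.0, 12.0),
        )
    return f, {"modality": kind}


def _sample_step3d(i, grid, rng):
    pattern = ("gaussian", "square")[i % 2]
    f = step_field(
        grid,
        pattern=pattern,
        levels=5,
        center=tuple(rng.uniform(-0.25, 0.25, size=2)),
        alpha=rng.uniform(4.0, 12.0),
    )
    return f, {"pattern": pattern, "levels": 5}


def _sample_brain_volume(rng, cfg):
    spec0 = BrainVolumeSpec(shape=cfg.brain_shape)
    a, b, c = spec0.semi_axes
    n_act = int(rng.integers(1, 4))
    acts = []
    for _ in range(n_act):
        # rejection-sample inside the 0.8-scaled ellipsoid so blobs do not
        # straddle the brain boundary
        while True:
            p = rng.uniform(-1.0, 1.0, size=3) * (0.8 * np.array([a, b, c]))
            if (p[0] / (0.8 * a)) ** 2 + (p[1] / (0.8 * b)) ** 2 + (
                p[2] / (0.8 * c)
            ) ** 2 <= 1.0:
                break
        acts.append(
            ActivationSpec(
                tuple(p),
                alpha=float(rng.uniform(20.0, 80.0)),
                amplitude=float(rng.uniform(0.6, 1.0)),
            )
        )
    return BrainVolumeSpec(shape=cfg.brain_shape, activations=tuple(acts))


# ---------------------------------------------------------------------------
# scenario assembly
# ---------------------------------------------------------------------------


def _split_indices(n, cfg, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    a, b = cfg.n_train, cfg.n_train + cfg.n_val
    return perm[:a], perm[a:b], perm[b : b + cfg.n_test]


def generate_scenario(
    name: str, config: Optional[ScenarioConfig] = None, seed: int = 0
) -> ScenarioDataset:
    """Deterministic dataset for one of the six scenarios.

    The same ``(config, seed)`` always yields bit-identical arrays.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    cfg = config or ScenarioConfig()
    geom_ss, noise_ss, split_ss = np.random.SeedSequence(seed).spawn(3)
    geom_rng = np.random.default_rng(geom_ss)
    noise_rng = np.random.default_rng(noise_ss)
    split_rng = np.random.default_rng(split_ss)

    if name == "brain3d":
        return _generate_brain3d(cfg, seed, geom_rng, noise_rng, split_rng)

    n = cfg.n_train + cfg.n_val + cfg.n_test
    grid = cfg.grid
    clean, noisy, meta = [], [], []
    for i in range(n):
        if name == "inclusion_size":
            f, md = _sample_inclusion_size(i, grid, geom_rng, cfg)
            sigma = cfg.sigma
        elif name == "geometry":
            f, md = _sample_geometry(i, grid, geom_rng, cfg)
            sigma = cfg.sigma
        elif name == "modality":
            f, md = _sample_modality_field(i, grid, geom_rng)
            sigma = cfg.sigma
        elif name == "noise":
            f, md = _sample_modality_field(i, grid, geom_rng)
            sigma = cfg.sigma_sweep[(i // 3) % len(cfg.sigma_sweep)]
        else:  # step3d
            f, md = _sample_step3d(i, grid, geom_rng)
            sigma = cfg.sigma
        nseed = int(noise_rng.integers(0, 2**31 - 1))
        g = add_gaussian_noise(f, NoiseSpec(sigma, seed=nseed))
        md = dict(md, sigma=float(sigma), noise_seed=nseed)
        clean.append(f.values)
        noisy.append(g.values)
        meta.append(md)
    tr, va, te = _split_indices(n, cfg, split_rng)
    return ScenarioDataset(
        name,
        np.stack(clean),
        np.stack(noisy),
        meta,
        tr,
        va,
        te,
        seed,
        grid,
    )


def _generate_brain3d(cfg, seed, geom_rng, noise_rng, split_rng) -> ScenarioDataset:
    n_tr, n_va, n_te = cfg.n_volumes
    n_vol = n_tr + n_va + n_te
    perm = split_rng.permutation(n_vol)
    vol_split = {}
    for rank, v in enumerate(perm):
        vol_split[int(v)] = (
            "train" if rank < n_tr else "val" if rank < n_tr + n_va else "test"
        )

    volumes = []
    clean, noisy, meta = [], [], []
    split_lists: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    min_cov = cfg.min_mask_coverage
    for v in range(n_vol):
        spec = _sample_brain_volume(geom_rng, cfg)
        vol = build_brain_volume(spec)
        nseed = int(noise_rng.integers(0, 2**31 - 1))
        noisy_vol = add_gaussian_noise(vol.values, NoiseSpec(cfg.sigma, seed=nseed))
        nz = spec.shape[2]
        npix = spec.shape[0] * spec.shape[1]
        z_keep = [
            k for k in range(nz) if vol.mask[:, :, k].sum() >= min_cov * npix
        ]
        which = vol_split[v]
        for k in z_keep:
            idx = len(clean)
            clean.append(vol.values[:, :, k])
            noisy.append(noisy_vol[:, :, k])
            meta.append({"volume": v, "z": k, "sigma": cfg.sigma, "split": which})
            split_lists[which].append(idx)
        volumes.append(
            {
                "clean": vol.values,
                "noisy": noisy_vol,
                "mask": vol.mask,
                "spec": spec,
                "split": which,
                "z_keep": z_keep,
                "noise_seed": nseed,
            }
        )
    grid = GridSpec(cfg.brain_shape[0], cfg.brain_shape[1])
    return ScenarioDataset(
        "brain3d",
        np.stack(clean),
        np.stack(noisy),
        meta,
        np.array(split_lists["train"], dtype=int),
        np.array(split_lists["val"], dtype=int),
        np.array(split_lists["test"], dtype=int),
        seed,
        grid,
        volumes=volumes,
    )


# ---------------------------------------------------------------------------
# archive I/O
# ---------------------------------------------------------------------------


def save_archive(ds: ScenarioDataset, path) -> None:
    """One compressed array archive per scenario: clean/noisy stacks, split
    index arrays and JSON-encoded metadata."""
    np.savez_compressed(
        path,
        name=np.array(ds.name),
        clean=ds.clean,
        noisy=ds.noisy,
        split_train=ds.train_idx,
        split_val=ds.val_idx,
        split_test=ds.test_idx,
        seed=np.array(ds.seed),
        grid=np.array([ds.grid.n_x, ds.grid.n_y]),
        metadata=np.array(json.dumps(ds.metadata)),
    )


def load_archive(path) -> ScenarioDataset:
    with np.load(path, allow_pickle=False) as z:
        nx, ny = (int(v) for v in z["grid"])
        return ScenarioDataset(
            str(z["name"]),
            z["clean"],
            z["noisy"],
            json.loads(str(z["metadata"])),
            z["split_train"],
            z["split_val"],
            z["split_test"],
            int(z["seed"]),
            GridSpec(nx, ny),
        )
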