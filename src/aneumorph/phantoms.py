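"""Voxel phantoms with analytically known morphology.

Phantoms stand in for patient segmentations: each generator voxelizes a
closed-form solid (sphere, ellipsoid, hemisphere-capped capsule, or a
sphere decorated with spherical blebs) on a grid of voxel centers and
returns the mask together with a *truth record* of every closed-form value
available for that shape.  Truth values are never computed by the
morphometry code, so they can serve as independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ResolutionError
from .meshing import VoxelMask

KINDS = ("sphere", "ellipsoid", "capsule", "sphere_with_blebs")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom; same spec + seed give a bitwise-identical mask."""

    kind: str = "sphere"
    radius_mm: float = 10.0
    semi_axes_mm: tuple[float, float, float] = (4.0, 2.0, 1.0)
    length_mm: float = 10.0  # cylinder section of a capsule
    n_blebs: int = 2
    bleb_radius_frac: float = 0.35
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    margin_voxels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; one of {KINDS}")
        if self.radius_mm <= 0 or self.length_mm <= 0:
            raise ValueError("size parameters must be positive")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")
        if not 0.0 < self.bleb_radius_frac < 1.0:
            raise ValueError("bleb radius fraction must be in (0, 1)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def min_feature_mm(self) -> float:
        if self.kind == "sphere":
            return self.radius_mm
        if self.kind == "ellipsoid":
            return min(self.semi_axes_mm)
        if self.kind == "capsule":
            return self.radius_mm
        return self.radius_mm * self.bleb_radius_frac


def make_phantom(spec: PhantomSpec) -> tuple[VoxelMask, dict]:
    """Voxelize a phantom and return ``(mask, truth)``.

    ``truth`` holds every closed-form morphology value available for the
    kind (see module docstring); missing entries mean no closed form
    exists.  Raises :class:`ResolutionError` when the smallest feature
    spans fewer than 4 voxels.
    """
    h = np.asarray(spec.spacing, dtype=float)
    if spec.min_feature_mm / h.max() < 4.0:
        raise ResolutionError(
            f"min feature {spec.min_feature_mm} mm spans < 4 voxels at "
            f"spacing {tuple(h)}; refine the grid"
        )
    inside, extent, truth = _solid(spec)
    rot = Rotation.from_euler("xyz", spec.rotation_deg, degrees=True)

    half = extent + spec.margin_voxels * h.max()
    shape = np.ceil(2.0 * half / h).astype(int) + 1
    axes = [np.arange(shape[i]) * h[i] - (shape[i] - 1) * h[i] / 2.0 for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    # rotate the shape, i.e. pull grid points back into the shape frame
    pts = grid.reshape(-1, 3) @ rot.as_matrix()  # R^T applied to each point
    values = inside(pts).reshape(shape)
    if not values.any():
        raise ResolutionError("phantom produced no foreground voxels")
    return VoxelMask(values=values, spacing=tuple(h)), truth


def _solid(spec: PhantomSpec):
    """Return ``(inside(points), bounding_half_extent_mm, truth_dict)``."""
    if spec.kind == "sphere":
        r = spec.radius_mm
        truth = {
            "volume_mm3": 4.0 / 3.0 * np.pi * r**3,
            "surface_area_mm2": 4.0 * np.pi * r**2,
            "sphericity": 1.0,
            "elongation": 1.0,
            "flatness": 1.0,
            "shape_index_median": 1.0,
            "curvedness_median": 1.0 / r,
        }
        return (lambda p: (p * p).sum(axis=1) <= r * r), r, truth

    if spec.kind == "ellipsoid":
        a, b, c = sorted(spec.semi_axes_mm, reverse=True)
        truth = {
            "volume_mm3": 4.0 / 3.0 * np.pi * a * b * c,
            "elongation": b / a,
            "flatness": c / a,
        }
        axes = np.array([a, b, c])

        def inside(p, axes=axes):
            q = p / axes
            return (q * q).sum(axis=1) <= 1.0

        return inside, a, truth

    if spec.kind == "capsule":
        r, length = spec.radius_mm, spec.length_mm
        truth = {
            "volume_mm3": np.pi * r * r * length + 4.0 / 3.0 * np.pi * r**3,
            "surface_area_mm2": 2.0 * np.pi * r * length + 4.0 * np.pi * r**2,
        }

        def inside(p, r=r, hl=length / 2.0):
            z = np.clip(p[:, 2], -hl, hl)
            d = p.copy()
            d[:, 2] -= z
            return (d * d).sum(axis=1) <= r * r

        return inside, length / 2.0 + r, truth

    # sphere_with_blebs
    r = spec.radius_mm
    rb = spec.bleb_radius_frac * r
    rng = np.random.default_rng(spec.seed)
    dirs = rng.normal(size=(spec.n_blebs, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    centers = dirs * r  # bleb centers on the parent surface
    truth = {
        "base_volume_mm3": 4.0 / 3.0 * np.pi * r**3,
        "base_surface_area_mm2": 4.0 * np.pi * r**2,
        "base_sphericity": 1.0,
    }

    def inside(p, r=r, rb=rb, centers=centers):
        out = (p * p).sum(axis=1) <= r * r
        for c in centers:
            d = p - c
            out |= (d * d).sum(axis=1) <= rb * rb
        return out

    return inside, r + rb, truth


@dataclass(frozen=True)
class PhantomSuite:
    """Deterministic catalog of (spec, mask, truth) triples for testing."""

    entries: tuple = field(default_factory=tuple)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def phantom_suite(resolutions, seed: int = 0) -> PhantomSuite:
    """Fixed phantom catalog voxelized at each of ``resolutions`` (mm).

    Includes a sphere, an ellipsoid, a capsule and a bleb-decorated sphere
    so that convergence and anisotropy behavior can be checked across
    resolutions.  Deterministic given ``seed``.
    """
    resolutions = [float(r) for r in resolutions]
    if len(resolutions) < 2:
        raise ValueError("need at least 2 resolutions for a convergence suite")
    entries = []
    for res in resolutions:
        spacing = (res, res, res)
        specs = [
            PhantomSpec(kind="sphere", radius_mm=10.0, spacing=spacing, seed=seed),
            PhantomSpec(
                kind="ellipsoid", semi_axes_mm=(8.0, 5.0, 4.0), spacing=spacing, seed=seed
            ),
            PhantomSpec(
                kind="capsule", radius_mm=4.0, length_mm=10.0, spacing=spacing, seed=seed
            ),
            PhantomSpec(
                kind="sphere_with_blebs",
                radius_mm=8.0,
                n_blebs=2,
                bleb_radius_frac=0.5,
                spacing=spacing,
                seed=seed,
            ),
        ]
        for sp in specs:
            mask, truth = make_phantom(sp)
            entries.append((sp, mask, truth))
    return PhantomSuite(entries=tuple(entries))


def write_truth_json(truth: dict, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump({k: float(v) for k, v in truth.items()}, fh, indent=2)
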