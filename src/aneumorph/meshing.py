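"""Binary segmentation masks -> harmonized watertight surface meshes.

The entry point for an analysis is a :class:`VoxelMask` (a binary grid plus
physical spacing in mm).  Masks are harmonized by resampling to a common
voxel size, reduced to their largest 26-connected component, and converted
to a triangle mesh with marching cubes.  Mesh integrals (volume by the
divergence theorem, surface area as the sum of triangle areas) operate on
the resulting :class:`SurfaceMesh`.

Coordinate convention: grid indices are 0-based and world coordinates are
``origin + index * spacing`` (axis order x, y, z).
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import EmptyMaskError, MeshTopologyError, ResolutionError

log = logging.getLogger(__name__)

#: 26-connectivity structuring element used for component labelling.
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class VoxelMask:
    """Binary 3D grid with physical spacing.

    Parameters
    ----------
    values
        Boolean array, shape (nx, ny, nz); ``True`` marks foreground.
    spacing
        mm per axis, all strictly positive.
    origin
        mm offset of the grid corner (voxel index (0,0,0)).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=bool)
        object.__setattr__(self, "values", values)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)
        if values.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={values.ndim}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {spacing}")
        if not values.any():
            raise EmptyMaskError("mask has no foreground voxels")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm³."""
        return float(np.prod(self.spacing))

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())

    def foreground_coordinates(self) -> np.ndarray:
        """World (mm) coordinates of foreground voxel centers, shape (n, 3)."""
        idx = np.argwhere(self.values).astype(float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def volume_estimate(self) -> float:
        """Voxel-counting volume estimate in mm³."""
        return self.foreground_count * self.voxel_volume


@dataclass(frozen=True)
class SurfaceMesh:
    """Watertight triangle mesh in mm coordinates with outward normals."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vertices = np.ascontiguousarray(self.vertices, dtype=float)
        faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        object.__setattr__(self, "vertices", vertices)
        object.__setattr__(self, "faces", faces)
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise ValueError("vertices must have shape (n, 3)")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must have shape (m, 3)")
        if self.normals is None:
            object.__setattr__(self, "normals", vertex_normals(vertices, faces))
        else:
            object.__setattr__(
                self, "normals", np.ascontiguousarray(self.normals, dtype=float)
            )

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def euler_characteristic(self) -> int:
        """V − E + F; equals 2 for genus-0 closed surfaces."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        n_edges = np.unique(edges, axis=0).shape[0]
        return self.n_vertices - n_edges + self.n_faces

    def is_watertight(self) -> bool:
        """True iff every undirected edge is shared by exactly two faces."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))


def vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted per-vertex unit normals from face winding."""
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    face_n = np.cross(v1 - v0, v2 - v0)  # magnitude = 2 * area
    normals = np.zeros_like(vertices)
    for i in range(3):
        np.add.at(normals, faces[:, i], face_n)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return normals / norm


# ---------------------------------------------------------------------------
# Mask operations
# ---------------------------------------------------------------------------

def resample_mask(
    mask: VoxelMask, target_spacing: tuple[float, float, float]
) -> VoxelMask:
    """Resample a binary mask to ``target_spacing``.

    The binary field is interpolated linearly and re-thresholded at 0.5, so
    foreground is preserved up to interpolation error.  The output grid
    covers the same physical extent as the input.
    """
    target = tuple(float(s) for s in target_spacing)
    if len(target) != 3 or any(s <= 0 for s in target):
        raise ValueError(f"target_spacing must be 3 positive reals, got {target}")
    if np.allclose(target, mask.spacing):
        return mask
    zoom = np.asarray(mask.spacing) / np.asarray(target)
    # grid_mode: voxels are cells, so the physical extent is preserved
    resampled = ndimage.zoom(
        mask.values.astype(np.float32), zoom=zoom, order=1,
        mode="grid-constant", grid_mode=True,
    )
    values = resampled >= 0.5
    if not values.any():
        raise ResolutionError(
            f"no foreground left after resampling to {target} mm; "
            "target spacing too coarse for this mask"
        )
    # cell semantics shift the first voxel center by half the spacing change
    origin = tuple(
        o + (t - s) / 2.0 for o, s, t in zip(mask.origin, mask.spacing, target)
    )
    return VoxelMask(values=values, spacing=target, origin=origin)


def largest_component(mask: VoxelMask) -> VoxelMask:
    """Keep only the largest 26-connected foreground component.

    Ties are broken in favor of the component containing the lowest
    flat-index foreground voxel.
    """
    labels, n = ndimage.label(mask.values, structure=_STRUCT_26)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    best = counts.max()
    tied = np.flatnonzero(counts == best)
    if tied.size > 1:
        # lowest-index seed voxel wins
        flat = labels.ravel()
        first = {lab: np.argmax(flat == lab) for lab in tied}
        keep = min(tied, key=lambda lab: first[lab])
        log.info("component-size tie (%d voxels); keeping lowest-seed component", best)
    else:
        keep = tied[0]
    return replace(mask, values=labels == keep)


def extract_mesh(
    mask: VoxelMask,
    level: float = 0.5,
    sigma_mm: float = 0.5,
    smoothing_iterations: int = 0,
) -> SurfaceMesh:
    """Extract a watertight surface mesh with marching cubes.

    The binary field is smoothed with a Gaussian of physical width
    ``sigma_mm`` before iso-surfacing (``sigma_mm=0`` disables this and
    meshes the raw binary grid).  Without smoothing, marching cubes on a
    binary grid produces staircase surfaces whose area is biased high by
    ~8% and whose curvature field is noise-dominated at any resolution, so
    a small physical sigma is the default.

    The mask is padded so that foreground touching the grid boundary still
    yields a closed surface.  Vertices are returned in mm world
    coordinates; faces wound so the signed volume is positive (outward
    normals).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    spacing = np.asarray(mask.spacing)
    if sigma_mm > 0:
        pad = int(max(1, np.ceil(3.0 * sigma_mm / spacing.min())))
        field = np.pad(mask.values.astype(np.float32), pad)
        field = ndimage.gaussian_filter(field, sigma=sigma_mm / spacing)
    else:
        pad = 1
        field = np.pad(mask.values.astype(np.float32), pad)
    verts, faces, _, _ = measure.marching_cubes(field, level=level, spacing=tuple(spacing))
    # undo padding offset, then shift into world coordinates
    verts = verts - pad * spacing + np.asarray(mask.origin)
    if _signed_volume(verts, faces) < 0:
        faces = faces[:, ::-1]
    if smoothing_iterations > 0:
        verts = _laplacian_smooth(verts, faces, smoothing_iterations)
    mesh = SurfaceMesh(vertices=verts, faces=np.ascontiguousarray(faces))
    if not mesh.is_watertight():
        raise MeshTopologyError("marching cubes produced a non-watertight mesh")
    return mesh


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def _laplacian_smooth(
    vertices: np.ndarray, faces: np.ndarray, iterations: int, lam: float = 0.5
) -> np.ndarray:
    from scipy.sparse import coo_matrix

    n = vertices.shape[0]
    edges = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    adj = coo_matrix((np.ones(i.size), (i, j)), shape=(n, n)).tocsr()
    adj.data[:] = 1.0
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    out = vertices.copy()
    for _ in range(iterations):
        out = out + lam * (adj @ out / deg[:, None] - out)
    return out


# ---------------------------------------------------------------------------
# Mesh integrals
# ---------------------------------------------------------------------------

def mesh_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume (mm³) by the divergence theorem; mesh must be watertight."""
    if not mesh.is_watertight():
        raise MeshTopologyError("volume requires a watertight mesh")
    vol = _signed_volume(mesh.vertices, mesh.faces)
    if vol <= 0:
        raise MeshTopologyError("signed volume is non-positive; check face winding")
    return vol


def mesh_surface_area(mesh: SurfaceMesh) -> float:
    """Total surface area (mm²); degenerate triangles contribute zero."""
    v0, v1, v2 = (mesh.vertices[mesh.faces[:, i]] for i in range(3))
    areas = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)
    n_degenerate = int((areas == 0).sum())
    if n_degenerate:
        log.warning("%d degenerate zero-area triangles", n_degenerate)
    return float(areas.sum())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_nifti_mask(path: str | Path) -> VoxelMask:
    """Read a binary mask from NIfTI; spacing from the header zooms."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return VoxelMask(values=data > 0, spacing=spacing, origin=origin)


def save_nifti_mask(mask: VoxelMask, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.values.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def save_ply(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a binary little-endian PLY file (vertices + faces)."""
    header = (
        "ply\nformat binary_little_endian 1.0\n"
        f"element vertex {mesh.n_vertices}\n"
        "property float x\nproperty float y\nproperty float z\n"
        f"element face {mesh.n_faces}\n"
        "property list uchar int vertex_indices\nend_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(mesh.vertices.astype("<f4").tobytes())
        face_block = np.empty((mesh.n_faces, 13), dtype=np.uint8)
        face_block[:, 0] = 3
        face_block[:, 1:] = (
            mesh.faces.astype("<i4").view(np.uint8).reshape(mesh.n_faces, 12)
        )
        fh.write(face_block.tobytes())


def save_stl(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a binary STL file."""
    v0, v1, v2 = (mesh.vertices[mesh.faces[:, i]] for i in range(3))
    fn = np.cross(v1 - v0, v2 - v0)
    norm = np.linalg.norm(fn, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    fn = fn / norm
    with open(path, "wb") as fh:
        fh.write(b"\0" * 80)
        fh.write(struct.pack("<I", mesh.n_faces))
        rec = np.zeros((mesh.n_faces, 50), dtype=np.uint8)
        tri = np.concatenate([fn, v0, v1, v2], axis=1).astype("<f4")
        rec[:, :48] = tri.view(np.uint8).reshape(mesh.n_faces, 48)
        fh.write(rec.tobytes())
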