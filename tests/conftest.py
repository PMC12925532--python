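import numpy as np
import pytest

from aneumorph.meshing import SurfaceMesh, VoxelMask


def make_sphere_mask(radius: float, spacing: float, margin: int = 3) -> VoxelMask:
    """Voxelized sphere centered on a voxel center (independent of phantoms)."""
    n = int(np.ceil(2 * (radius + margin * spacing) / spacing)) | 1
    idx = np.arange(n) * spacing
    c = idx[n // 2]
    x, y, z = np.meshgrid(idx, idx, idx, indexing="ij")
    values = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius**2
    return VoxelMask(values=values, spacing=(spacing,) * 3)


def unit_cube_mesh() -> SurfaceMesh:
    """Hand-built unit cube: 8 vertices, 12 outward-wound triangles."""
    v = np.array(
        [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    )
    # vertex index = 4x + 2y + z
    f = np.array(
        [
            [0, 1, 3], [0, 3, 2],  # x=0 face, normal -x
            [4, 7, 5], [4, 6, 7],  # x=1 face, normal +x
            [0, 5, 1], [0, 4, 5],  # y=0
            [2, 3, 7], [2, 7, 6],  # y=1
            [0, 2, 6], [0, 6, 4],  # z=0
            [1, 5, 7], [1, 7, 3],  # z=1
        ]
    )
    return SurfaceMesh(vertices=v, faces=f)


def icosphere_mesh(radius: float, subdivisions: int = 4) -> SurfaceMesh:
    """Analytic sphere mesh by icosahedron subdivision (marching-cubes free)."""
    t = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    for _ in range(subdivisions):
        edge_mid: dict = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in edge_mid:
                verts_list.append((verts_list[i] + verts_list[j]) / 2.0)
                edge_mid[key] = len(verts_list) - 1
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces)
    verts = verts / np.linalg.norm(verts, axis=1, keepdims=True) * radius
    return SurfaceMesh(vertices=verts, faces=faces)


@pytest.fixture(scope="session")
def sphere_mask_r10_h05() -> VoxelMask:
    return make_sphere_mask(10.0, 0.5)


@pytest.fixture(scope="session")
def sphere_mesh_r10_h05(sphere_mask_r10_h05):
    from aneumorph.meshing import extract_mesh

    return extract_mesh(sphere_mask_r10_h05)


@pytest.fixture(scope="session")
def cube_mesh() -> SurfaceMesh:
    return unit_cube_mesh()


@pytest.fixture(scope="session")
def cohort_small():
    from aneumorph.cohort import SimulationParams, generate_cohort

    return generate_cohort(SimulationParams(n=326, seed=11))


@pytest.fixture(scope="session")
def cohort_large():
    from aneumorph.cohort import SimulationParams, generate_cohort

    return generate_cohort(SimulationParams(n=10_000, seed=5))
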