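import numpy as np
import pytest


def ball(radius: float, n: int, center=None) -> np.ndarray:
    g = np.ogrid[:n, :n, :n]
    c = [(n - 1) / 2] * 3 if center is None else center
    return sum((x - ci) ** 2 for x, ci in zip(g, c)) <= radius * radius


def ball_at(shape, center, radius) -> np.ndarray:
    g = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return sum((x - ci) ** 2 for x, ci in zip(g, center)) <= radius * radius


def solid_tube(length=32, radius=3.0, n_cross=12) -> np.ndarray:
    tube = np.zeros((length + 8, n_cross, n_cross), bool)
    g = np.ogrid[:n_cross, :n_cross]
    c = (n_cross - 1) / 2
    disc = (g[0] - c) ** 2 + (g[1] - c) ** 2 <= radius * radius
    tube[4:4 + length] = disc[None]
    return tube


def torus(n=30, ring_radius=8.0, tube_radius=3.0) -> np.ndarray:
    x, y, z = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    rho = np.sqrt((x - c) ** 2 + (y - c) ** 2)
    return (rho - ring_radius) ** 2 + (z - c) ** 2 <= tube_radius ** 2


def dumbbell(shape=(40, 20, 20), r=7, bridge=(16, 24)) -> np.ndarray:
    db = ball_at(shape, (9, 9, 9), r) | ball_at(shape, (30, 9, 9), r)
    db[bridge[0]:bridge[1], 8:11, 8:11] = True
    return db


def boundary_euler(F: np.ndarray) -> int:
    """Independent mesh oracle: Euler characteristic of the boundary
    surface extracted by marching cubes (2 - 2*genus per component)."""
    import trimesh
    from skimage.measure import marching_cubes

    verts, faces, _, _ = marching_cubes(np.pad(F, 1).astype(np.float32),
                                        level=0.5)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    return int(mesh.euler_number)


@pytest.fixture(scope="session")
def shape_suite():
    """Named binary shapes with known (components, cavities, tunnels)."""
    rng = np.random.default_rng(7)
    shapes = {
        "ball": (ball(10, 28), (1, 0, 0)),
        "slab": (np.pad(np.ones((28, 28, 9), bool), 4), (1, 0, 0)),
        "tube": (solid_tube(), (1, 0, 0)),
        "torus": (torus(), (1, 0, 1)),
        "hollow_sphere": (ball(10, 28) & ~ball(6, 28), (1, 1, 0)),
        "dumbbell": (dumbbell(), (1, 0, 0)),
    }
    for i in range(4):
        blob = np.zeros((36, 36, 36), bool)
        for _ in range(4):
            ctr = rng.integers(8, 28, 3)
            blob |= ball_at((36, 36, 36), ctr, rng.integers(4, 9))
        shapes[f"blobs_{i}"] = (blob, None)  # counts computed on demand
    return shapes


@pytest.fixture(scope="session")
def clean_phantom():
    from headmodel.phantom import PhantomSpec, make_layered_phantom

    spec = PhantomSpec(shape=(72, 72, 72))
    vol, lab = make_layered_phantom(spec)
    return spec, vol, lab


@pytest.fixture(scope="session")
def degraded_phantom64():
    from headmodel.phantom import PhantomSpec, degraded_phantom

    spec = PhantomSpec(shape=(64, 64, 64), inu_percent=20.0,
                       noise_percent=3.0, seed=0)
    vol, lab = degraded_phantom(spec)
    return spec, vol, lab
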