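"""Synthetic layered head phantoms with ground truth.

The generator emulates the image properties a T1-weighted head scan presents
to the segmentation pipeline: concentric tissue layers (flesh / skull / CSF /
GM / WM from outside in), eyeballs, a multiplicative low-frequency intensity
inhomogeneity (bias) field, Rician noise in signal regions with Rayleigh
noise in the air background, optional injected topological handles on the
white matter, and a quasi-spherical EEG sensor cloud around the scalp.

Intensity ordering follows the T1 a-priori observation skull < CSF < GM < WM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# ---------------------------------------------------------------------------
# tissue label codes (shared across the whole package)
# ---------------------------------------------------------------------------


class Tissue:
    """Integer label codes for head tissues."""

    BACKGROUND = 0
    FLESH = 1
    BONE = 2
    CSF = 3
    GM = 4
    WM = 5
    EYEBALL = 6
    # partitioned brain compartments (cascade output)
    WM_LEFT = 7
    WM_RIGHT = 8
    WM_CEREBELLAR = 9
    GM_LEFT = 10
    GM_RIGHT = 11
    GM_CEREBELLAR = 12

    NAMES = {
        0: "background", 1: "flesh", 2: "bone", 3: "csf", 4: "gm", 5: "wm",
        6: "eyeball", 7: "wm_left", 8: "wm_right", 9: "wm_cerebellar",
        10: "gm_left", 11: "gm_right", 12: "gm_cerebellar",
    }

    WM_ALL = (5, 7, 8, 9)
    GM_ALL = (4, 10, 11, 12)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and world origin (mm).

    World coordinate of index (i, j, k) is ``origin + index * spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D")
        if min(self.data.shape) < 1:
            raise ValueError("all dims must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume values must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def like(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.spacing, self.origin)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class LabelVolume(Volume):
    """Voxel-wise tissue labels on the same grid conventions as Volume."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = self.data.astype(np.int16)

    def mask(self, *labels: int) -> np.ndarray:
        return np.isin(self.data, labels)


@dataclass
class BiasField:
    """Multiplicative, slowly varying intensity-inhomogeneity field."""

    field: np.ndarray
    half_range: float  # e.g. 0.10 for a 20 % level (values in [0.90, 1.10])

    def __post_init__(self) -> None:
        if np.any(self.field <= 0):
            raise ValueError("bias field must be strictly positive")


@dataclass
class SensorCloud:
    """Labeled 3D sensor positions (mm) with optional fiducials."""

    labels: list[str]
    points: np.ndarray  # (n, 3) mm
    fiducials: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.labels) < 3:
            raise ValueError("a sensor cloud needs at least 3 points")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("sensor labels must be unique")
        if self.points.shape != (len(self.labels), 3):
            raise ValueError("points must be (n, 3) matching labels")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("sensor coordinates must be finite")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class PhantomSpec:
    """Geometry, intensity and degradation parameters of a layered phantom.

    Radii are in mm, strictly nested WM < GM < CSF < skull < flesh. The GM
    shell is thin relative to the head (near-uniform cortex thickness).
    Tissue means satisfy the T1 ordering bone < CSF < GM < WM.
    """

    shape: tuple[int, int, int] = (72, 72, 72)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    r_wm: float = 20.0
    r_gm: float = 25.0
    r_csf: float = 27.0
    r_skull: float = 31.0
    r_flesh: float = 35.0
    eyeballs: bool = True
    eyeball_radius: float = 5.0
    means: dict[str, float] = field(
        default_factory=lambda: {
            "wm": 150.0, "gm": 105.0, "csf": 40.0,
            "bone": 20.0, "flesh": 80.0, "eyeball": 60.0,
            "background": 5.0,
        }
    )
    noise_percent: float = 0.0
    inu_percent: float = 0.0
    n_handles: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        radii = [self.r_wm, self.r_gm, self.r_csf, self.r_skull, self.r_flesh]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError(
                "layer radii must be strictly nested: "
                "WM < GM < CSF < skull < flesh"
            )
        m = self.means
        if not (m["bone"] < m["csf"] < m["gm"] < m["wm"]):
            raise ValueError(
                "tissue means must satisfy the T1 ordering "
                "bone < CSF < GM < WM"
            )
        if self.noise_percent < 0 or self.inu_percent < 0:
            raise ValueError("noise/INU percentages must be non-negative")
        if self.n_handles < 0:
            raise ValueError("n_handles must be non-negative")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _radius_grid(shape, spacing, center_mm):
    coords = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    r2 = sum((c - c0) ** 2 for c, c0 in zip(coords, center_mm))
    return np.sqrt(r2)


def make_layered_phantom(spec: PhantomSpec) -> tuple[Volume, LabelVolume]:
    """Build the piecewise-constant intensity volume and ground-truth labels.

    The intensity volume is exactly the tissue mean at every voxel (the
    background mean in air); apply :func:`apply_bias_field` and
    :func:`add_noise` for degraded images. Handles are injected on the WM
    component when ``spec.n_handles > 0``.
    """
    shape, spacing = spec.shape, spec.spacing
    center = tuple((n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    r = _radius_grid(shape, spacing, center)

    labels = np.full(shape, Tissue.BACKGROUND, dtype=np.int16)
    labels[r < spec.r_flesh] = Tissue.FLESH
    labels[r < spec.r_skull] = Tissue.BONE
    labels[r < spec.r_csf] = Tissue.CSF
    labels[r < spec.r_gm] = Tissue.GM
    labels[r < spec.r_wm] = Tissue.WM

    if spec.eyeballs:
        # anterior (max y), lateral, at brain-center height; clamped so the
        # spheres stay inside the field of view even when the outer shells
        # are clipped by it
        ey = center[1] + spec.r_flesh - spec.eyeball_radius * 0.8
        ey = min(ey, (shape[1] - 1) * spacing[1] - spec.eyeball_radius - 1)
        ex_off = spec.r_flesh * 0.35
        for sx in (-1.0, 1.0):
            c_eye = (center[0] + sx * ex_off, ey, center[2])
            re = _radius_grid(shape, spacing, c_eye)
            labels[re < spec.eyeball_radius] = Tissue.EYEBALL

    lab = LabelVolume(labels, spacing)
    if spec.n_handles > 0:
        lab = add_handles(lab, spec.n_handles, spec.seed)

    mean_of = {
        Tissue.BACKGROUND: spec.means["background"],
        Tissue.FLESH: spec.means["flesh"],
        Tissue.BONE: spec.means["bone"],
        Tissue.CSF: spec.means["csf"],
        Tissue.GM: spec.means["gm"],
        Tissue.WM: spec.means["wm"],
        Tissue.EYEBALL: spec.means["eyeball"],
    }
    intensity = np.zeros(shape, dtype=np.float64)
    for code, mu in mean_of.items():
        intensity[lab.data == code] = mu
    return Volume(intensity, spacing), lab


def degraded_phantom(spec: PhantomSpec) -> tuple[Volume, LabelVolume]:
    """Phantom with the bias field and noise of ``spec`` applied."""
    vol, lab = make_layered_phantom(spec)
    if spec.inu_percent > 0:
        vol, _ = apply_bias_field(vol, spec.inu_percent, spec.seed,
                                  brain_mask=lab.mask(*Tissue.WM_ALL,
                                                      *Tissue.GM_ALL,
                                                      Tissue.CSF))
        vol.data[lab.data == Tissue.BACKGROUND] = spec.means["background"]
    if spec.noise_percent > 0:
        vol = add_noise(vol, lab, spec.noise_percent, spec.seed + 1,
                        wm_mean=spec.means["wm"])
    return vol, lab


# ---------------------------------------------------------------------------
# bias field
# ---------------------------------------------------------------------------


def apply_bias_field(
    vol: Volume, inu_percent: float, seed: int = 0,
    brain_mask: np.ndarray | None = None,
) -> tuple[Volume, BiasField]:
    """Multiply by a slowly varying bias field of the stated half-range.

    For an ``inu_percent`` of 20 the field spans exactly [0.90, 1.10] over
    the brain mask (whole grid when no mask given); other levels scale the
    range linearly. Realized as a sum of three low-frequency cosines with a
    seeded orientation, rescaled over the mask — an analytically smooth
    stand-in for coil shading.
    """
    if inu_percent < 0:
        raise ValueError("inu_percent must be >= 0")
    if inu_percent == 0:
        f = np.ones_like(vol.data, dtype=float)
        return vol.like(vol.data.copy()), BiasField(f, 0.0)

    rng = np.random.default_rng(seed)
    shape = vol.shape
    coords = np.meshgrid(
        *[np.linspace(0.0, 1.0, n) for n in shape], indexing="ij"
    )
    raw = np.zeros(shape, dtype=float)
    for _ in range(3):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        phase = rng.uniform(0, 2 * np.pi)
        # at most half a period across the grid: slowly varying by design
        arg = sum(d * c for d, c in zip(direction, coords))
        raw += np.cos(np.pi * arg + phase)

    mask = np.ones(shape, bool) if brain_mask is None else brain_mask
    half = inu_percent / 200.0  # 20 % -> 0.10
    lo, hi = raw[mask].min(), raw[mask].max()
    if hi - lo < 1e-12:
        f = np.ones(shape, float)
    else:
        f = 1.0 - half + (raw - lo) * (2 * half) / (hi - lo)
    f = np.clip(f, 1e-3, None)
    return vol.like(vol.data * f), BiasField(f, half)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------


def add_noise(
    vol: Volume, labels: LabelVolume, noise_percent: float, seed: int = 0,
    wm_mean: float | None = None,
) -> Volume:
    """Rician noise in signal regions, Rayleigh in the background.

    ``noise_percent`` is the Gaussian sigma as a percentage of the WM mean
    (the reference tissue). A magnitude image is emulated: signal voxels
    become |y + n1 + i*n2| and background voxels |n1 + i*n2|.
    """
    if noise_percent < 0:
        raise ValueError("noise_percent must be >= 0")
    if vol.shape != labels.shape:
        raise ValueError("volume and label shapes differ")
    if noise_percent == 0:
        return vol.like(vol.data.copy())
    if wm_mean is None:
        wm = labels.mask(*Tissue.WM_ALL)
        if not wm.any():
            raise ValueError("no WM voxels to define the reference signal")
        wm_mean = float(vol.data[wm].mean())
    sigma = noise_percent / 100.0 * wm_mean
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, vol.shape)
    n2 = rng.normal(0.0, sigma, vol.shape)
    bg = labels.data == Tissue.BACKGROUND
    out = np.empty_like(vol.data, dtype=float)
    out[~bg] = np.hypot(vol.data[~bg] + n1[~bg], n2[~bg])
    out[bg] = np.hypot(n1[bg], n2[bg])
    return vol.like(out)


# ---------------------------------------------------------------------------
# topological handles
# ---------------------------------------------------------------------------


def add_handles(labels: LabelVolume, n_handles: int, seed: int = 0,
                thickness: int = 1) -> LabelVolume:
    """Attach thin WM bridges that each raise the WM genus by one.

    Each handle is an axis-aligned staple (two legs plus a bridge) planted on
    the WM surface so that the loop it closes with the WM body cannot be
    contracted. Legs and bridge are ``thickness`` voxels thick (<= 2).
    """
    if n_handles < 0:
        raise ValueError("n_handles must be >= 0")
    if n_handles == 0:
        return replace(labels, data=labels.data.copy())
    if thickness not in (1, 2):
        raise ValueError("handle thickness must be 1 or 2")
    wm = labels.mask(*Tissue.WM_ALL)
    if not wm.any():
        raise ValueError("no WM component to attach handles to")

    from .topology import count_topology

    rng = np.random.default_rng(seed)
    data = labels.data.copy()
    placed_total = 0
    # try each face of the object: rotate so the face looks up (+z),
    # place staples on top, rotate back
    for rot_axes, k in ((None, 0), ((2, 0), 1), ((2, 0), 2), ((2, 0), 3),
                        ((2, 1), 1), ((2, 1), 3)):
        if placed_total >= n_handles:
            break
        view = data if rot_axes is None else np.rot90(data, k, rot_axes)
        view = np.ascontiguousarray(view)
        got = _place_staples_on_top(
            view, n_handles - placed_total, rng, thickness, count_topology
        )
        placed_total += got
        data = view if rot_axes is None else np.rot90(view, -k, rot_axes)
        data = np.ascontiguousarray(data)
    if placed_total < n_handles:
        raise RuntimeError(
            f"could not place {n_handles} handles (placed {placed_total})"
        )
    return replace(labels, data=data)


def _place_staples_on_top(data, n_handles, rng, thickness, count_topology):
    """Place up to n_handles staples on the +z surface of the WM in-place."""
    wm = np.isin(data, Tissue.WM_ALL)
    shape = data.shape
    placed = 0
    zs = np.arange(shape[2])
    # top[x, y] = highest z with WM in that column, -1 when none
    top = np.max(np.where(wm, zs[None, None, :], -1), axis=2)
    base_cols = np.argwhere(top >= 0)
    cols = np.concatenate(
        [np.column_stack([base_cols, np.full(len(base_cols), o)])
         for o in (0, 1)]
    )
    rng.shuffle(cols)
    gap = 4  # leg separation along the staple axis
    h = 3    # bridge clearance above the surface
    t = thickness
    _, _, base_tunnels = count_topology(np.isin(data, Tissue.WM_ALL))
    for x, y, orient in cols:
        if placed >= n_handles:
            break
        z0 = top[x, y]
        # staple spans `gap` voxels along `orient`, `t` across
        dx, dy = (gap, t - 1) if orient == 0 else (t - 1, gap)
        if (x < 1 or y < 1 or x + dx + t >= shape[0]
                or y + dy + t >= shape[1]):
            continue
        win = top[x - 1:x + dx + t + 1, y - 1:y + dy + t + 1]
        # near-flat neighborhood keeps the staple's WM contact at its feet
        if win.min() < 0 or win.max() - z0 > 1 or z0 - win.min() > 1:
            continue
        zb = int(win.max()) + h
        if zb + t >= shape[2]:
            continue
        region = np.zeros(shape, bool)
        if orient == 0:
            region[x:x + t, y:y + t, z0 + 1:zb + t] = True           # leg 1
            region[x + gap:x + gap + t, y:y + t,
                   top[x + gap, y] + 1:zb + t] = True                # leg 2
            region[x:x + gap + t, y:y + t, zb:zb + t] = True         # bridge
        else:
            region[x:x + t, y:y + t, z0 + 1:zb + t] = True
            region[x:x + t, y + gap:y + gap + t,
                   top[x, y + gap] + 1:zb + t] = True
            region[x:x + t, y:y + gap + t, zb:zb + t] = True
        if np.any(wm[region]):
            continue  # staple may displace other tissue but never WM
        saved = data[region].copy()
        data[region] = Tissue.WM
        _, _, tun = count_topology(np.isin(data, Tissue.WM_ALL))
        if tun != base_tunnels + placed + 1:
            data[region] = saved  # did not add exactly one handle; revert
            continue
        placed += 1
        wm |= region
        # block the footprint (and a small margin) from being reused;
        # the exact-genus verification above rejects interacting staples
        top[max(0, x - 2):x + dx + t + 2,
            max(0, y - 2):y + dy + t + 2] = -1
    return placed


# ---------------------------------------------------------------------------
# sensor cloud
# ---------------------------------------------------------------------------


def make_sensor_cloud(
    labels: LabelVolume, n_sensors: int = 128, jitter_mm: float = 0.0,
    seed: int = 0, radius_factor: float = 1.0,
) -> SensorCloud:
    """Quasi-uniform sensors on a sphere around the scalp, plus fiducials.

    Sensor positions come from a Fibonacci spiral on the sphere circumscribing
    the head mask (scaled by ``radius_factor``), with optional isotropic
    Gaussian jitter. Fiducials are anatomical proxies: nasion = anterior-most
    scalp voxel, periauricular L/R = lateral extrema, vertex = superior-most.
    """
    if n_sensors < 4:
        raise ValueError("need at least 4 sensors")
    head = labels.data != Tissue.BACKGROUND
    if not head.any():
        raise ValueError("head mask is empty")
    idx = np.argwhere(head)
    world = labels.index_to_world(idx)
    centroid = world.mean(axis=0)
    radius = np.linalg.norm(world - centroid, axis=1).max() * radius_factor

    golden = np.pi * (3.0 - np.sqrt(5.0))

    def fibonacci(m):
        i = np.arange(m, dtype=float)
        z = 1.0 - 2.0 * (i + 0.5) / m
        rho = np.sqrt(1.0 - z * z)
        theta = golden * i
        return np.stack([rho * np.cos(theta), rho * np.sin(theta), z],
                        axis=1)

    if n_sensors % 2 == 0:
        # antipodal symmetrization: the unit vectors sum to zero exactly,
        # so all sensors are equidistant from the cloud centroid
        half = fibonacci(n_sensors // 2)
        units = np.vstack([half, -half])
    else:
        units = fibonacci(n_sensors)
    pts = units * radius + centroid
    if jitter_mm > 0:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, jitter_mm, pts.shape)

    fid = {
        "nasion": world[np.argmax(world[:, 1])],
        "periauricular_left": world[np.argmin(world[:, 0])],
        "periauricular_right": world[np.argmax(world[:, 0])],
        "vertex": world[np.argmax(world[:, 2])],
    }
    names = [f"E{k + 1}" for k in range(n_sensors)]
    return SensorCloud(names, pts, fid)
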