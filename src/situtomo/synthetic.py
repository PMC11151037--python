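"""Synthetic phantoms and loading curves with known ground truth.

Every analysis stage of the pipeline can be exercised on data produced
here: meniscus-like volumes of bright cylindrical fibers with controlled
orientation distributions, cartilage-like volumes with ellipsoidal
chondrocyte inclusions whose density and shape vary with depth,
standard-linear-solid (SLS) force responses to the compression protocols,
and repeated-scan pairs differing only in noise and a small rigid shift.

Ground truth (per-fiber angles, cell label masks, analytic moduli) is
emitted alongside every phantom; analysis code never reads it — it exists
only so tests and validation scripts can score recovery.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_core import DEFAULT_VOXEL_SIZE_UM, LoadingRecord, Volume3D, logger
from .mechanics import ProtocolSpec, sls_ramp_stress, strain_timeline

# ---------------------------------------------------------------------------
# Angle distributions
# ---------------------------------------------------------------------------
#
# A distribution is a tuple: ("delta", angle_deg), ("vonmises", mu_deg, kappa)
# or ("uniform",).  Azimuth lives on [0, 180) (axial); elevation on
# [-90, 90].  For elevation, "uniform" means uniform over the *sphere* —
# sin(theta) ~ U(-1, 1) — so that jointly-uniform azimuth/elevation specs
# produce isotropic fiber directions whose elevation density is
# proportional to cos(theta).


def _sample_azimuth(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "delta":
        return np.full(n, float(dist[1]) % 180.0)
    if kind == "uniform":
        return rng.uniform(0.0, 180.0, n)
    if kind == "vonmises":
        mu_deg, kappa = float(dist[1]), float(dist[2])
        # axial von Mises: sample on the doubled-angle circle, halve back
        ang = rng.vonmises(np.deg2rad(2 * mu_deg), kappa, n)
        return (np.rad2deg(ang) / 2.0) % 180.0
    raise ValueError(f"unknown azimuth distribution {dist!r}")


def _sample_elevation(dist: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "delta":
        theta = np.full(n, float(dist[1]))
        if np.any(np.abs(theta) > 90):
            raise ValueError("delta elevation outside [-90, 90]")
        return theta
    if kind == "uniform":
        return np.rad2deg(np.arcsin(rng.uniform(-1.0, 1.0, n)))
    if kind == "vonmises":
        mu_deg, kappa = float(dist[1]), float(dist[2])
        theta = np.rad2deg(rng.vonmises(np.deg2rad(mu_deg), kappa, n))
        return np.clip(theta, -90.0, 90.0)
    raise ValueError(f"unknown elevation distribution {dist!r}")


def angles_to_unit_vector(azimuth_deg, elevation_deg) -> np.ndarray:
    """Map (phi, theta) to unit vectors in (z, y, x) component order.

    phi is the in-plane angle from +x in the x-y plane, theta the angle
    from that plane toward +z.
    """
    phi = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    theta = np.deg2rad(np.asarray(elevation_deg, dtype=float))
    dx = np.cos(theta) * np.cos(phi)
    dy = np.cos(theta) * np.sin(phi)
    dz = np.sin(theta)
    return np.stack([dz, dy, dx], axis=-1)


# ---------------------------------------------------------------------------
# Fiber phantom
# ---------------------------------------------------------------------------


@dataclass
class FiberPhantomSpec:
    """Parameters of a meniscus-like fiber phantom.

    ``azimuth_deg``/``elevation_deg`` are distribution tuples (see module
    notes).  ``fiber_radius_um`` is a (min, max) range sampled uniformly
    per fiber.  Intensities are arbitrary units; ``noise_sd`` is the
    standard deviation of additive Gaussian noise.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    fiber_radius_um: tuple[float, float] = (8.25, 8.25)  # 3 voxels at 2.75 um
    n_fibers: int = 30
    azimuth_deg: tuple = ("delta", 0.0)
    elevation_deg: tuple = ("delta", 0.0)
    fiber_intensity: float = 1.0
    matrix_intensity: float = 0.0
    noise_sd: float = 0.0
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fiber_intensity == self.matrix_intensity:
            raise ValueError("fiber and matrix intensities must differ")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_fibers < 1:
            raise ValueError("need at least one fiber")


def gen_fiber_phantom(spec: FiberPhantomSpec) -> tuple[Volume3D, pd.DataFrame]:
    """Rasterize straight cylindrical fibers with known orientations.

    Fibers are anti-aliased cylinder distance fields thresholded at the
    radius (the voxel weight ramps linearly over one voxel at the wall),
    which avoids stair-step bias in downstream orientation estimates.
    Returns the volume (its ``mask`` marks fiber-interior voxels) and a
    truth table with one row per fiber: azimuth, elevation, radius.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    n = spec.n_fibers

    phi = _sample_azimuth(spec.azimuth_deg, n, rng)
    theta = _sample_elevation(spec.elevation_deg, n, rng)
    radii_vox = rng.uniform(*spec.fiber_radius_um, n) / spec.voxel_size_um
    if np.any(radii_vox < 1):
        logger.warning("gen_fiber_phantom: %d fiber(s) below 1 voxel radius (sub-resolution)",
                       int(np.sum(radii_vox < 1)))
    dirs = angles_to_unit_vector(phi, theta)  # (n, 3) in (z, y, x)
    centers = np.column_stack(
        [rng.uniform(0, nz, n), rng.uniform(0, ny, n), rng.uniform(0, nx, n)]
    )

    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=np.float32),
        np.arange(ny, dtype=np.float32),
        np.arange(nx, dtype=np.float32),
        indexing="ij",
    )
    weight = np.zeros(spec.shape, dtype=np.float32)
    for i in range(n):
        pz = zz - centers[i, 0]
        py = yy - centers[i, 1]
        px = xx - centers[i, 2]
        proj = pz * dirs[i, 0] + py * dirs[i, 1] + px * dirs[i, 2]
        d2 = (pz - proj * dirs[i, 0]) ** 2 + (py - proj * dirs[i, 1]) ** 2 + (
            px - proj * dirs[i, 2]
        ) ** 2
        w = np.clip(radii_vox[i] + 0.5 - np.sqrt(d2), 0.0, 1.0)
        np.maximum(weight, w, out=weight)

    data = spec.matrix_intensity + (spec.fiber_intensity - spec.matrix_intensity) * weight
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, spec.shape).astype(np.float32)
    truth = pd.DataFrame(
        {"azimuth_deg": phi, "elevation_deg": theta, "radius_vox": radii_vox}
    )
    vol = Volume3D(
        data=data.astype(np.float32),
        voxel_size_um=spec.voxel_size_um,
        mask=weight >= 0.5,
        meta={"phantom": "fiber", "seed": spec.seed},
    )
    return vol, truth


# ---------------------------------------------------------------------------
# Cartilage phantom
# ---------------------------------------------------------------------------


@dataclass
class CartilagePhantomSpec:
    """Parameters of a cartilage-like phantom with depth-varying cells.

    ``depth_density_profile`` holds the target chondrocyte volume fraction
    (percent) for each of the 10 depth layers, surface first.
    ``cell_axes_um`` gives ellipsoid semi-axes (z, y, x) in micrometres:
    either one triple used everywhere, or a (surface, deep) pair that is
    interpolated linearly with depth — flattened discoidal cells near the
    articular surface, rounder cells in the deep zone.
    """

    shape: tuple[int, int, int] = (120, 96, 96)
    depth_density_profile: Sequence[float] = (5.0,) * 10
    cell_axes_um: Sequence = ((4.0, 10.0, 10.0), (9.0, 7.0, 7.0))
    cell_intensity: float = 0.3
    matrix_intensity: float = 0.7
    noise_sd: float = 0.0
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    seed: int = 0
    max_tries_per_cell: int = 200

    def __post_init__(self) -> None:
        prof = np.asarray(self.depth_density_profile, dtype=float)
        if np.any(prof < 0) or np.any(prof > 30):
            raise ValueError("target layer densities must lie in [0, 30] percent")
        if self.cell_intensity == self.matrix_intensity:
            raise ValueError("cell and matrix intensities must differ")


def _layer_axes_vox(spec: CartilagePhantomSpec, n_layers: int) -> np.ndarray:
    axes = np.asarray(spec.cell_axes_um, dtype=float)
    if axes.ndim == 1:
        per_layer = np.tile(axes, (n_layers, 1))
    elif axes.shape == (2, 3):
        frac = np.linspace(0, 1, n_layers)[:, None]
        per_layer = axes[0] * (1 - frac) + axes[1] * frac
    elif axes.shape == (n_layers, 3):
        per_layer = axes
    else:
        raise ValueError("cell_axes_um must be one triple, a (surface, deep) pair, or per-layer")
    return per_layer / spec.voxel_size_um


def _try_place_ellipsoid(label: np.ndarray, center: np.ndarray, semi: np.ndarray) -> int:
    """Add an ellipsoid to the label mask unless it overlaps an existing cell.

    Returns the number of voxels added (0 when the candidate overlapped).
    """
    lo = np.maximum(np.floor(center - semi).astype(int), 0)
    hi = np.minimum(np.ceil(center + semi + 1).astype(int), label.shape)
    grids = np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij")
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    inside = q <= 1.0
    region = label[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    if (inside & region).any():
        return 0
    region |= inside
    return int(inside.sum())


def gen_cartilage_phantom(spec: CartilagePhantomSpec) -> tuple[Volume3D, np.ndarray]:
    """Place non-overlapping ellipsoidal cells to hit per-layer densities.

    Cells are added layer by layer (centers kept inside their layer) until
    the realized volume fraction of the truth label mask reaches the layer
    target; realized density lands within about one percentage point of the
    target.  Returns the noisy grayscale volume and the boolean truth mask.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    targets = np.asarray(spec.depth_density_profile, dtype=float)
    n_layers = len(targets)
    bounds = np.linspace(0, nz, n_layers + 1).round().astype(int)
    axes_vox = _layer_axes_vox(spec, n_layers)

    label = np.zeros(spec.shape, dtype=bool)
    for li in range(n_layers):
        z0, z1 = bounds[li], bounds[li + 1]
        layer_vox = (z1 - z0) * ny * nx
        target_vox = targets[li] / 100.0 * layer_vox
        semi = axes_vox[li]
        cell_vol = 4.0 / 3.0 * np.pi * np.prod(semi)
        budget = spec.max_tries_per_cell * max(1, int(np.ceil(target_vox / cell_vol)))
        placed_vox = 0
        tries = 0
        while placed_vox < target_vox:
            if tries > budget:
                raise RuntimeError(
                    f"layer {li}: cannot reach {targets[li]}% density without overlap"
                )
            tries += 1
            center = np.array(
                [
                    rng.uniform(z0 + semi[0], max(z0 + semi[0], z1 - semi[0])),
                    rng.uniform(semi[1], ny - semi[1]),
                    rng.uniform(semi[2], nx - semi[2]),
                ]
            )
            placed_vox += _try_place_ellipsoid(label, center, semi)

    data = np.full(spec.shape, spec.matrix_intensity, dtype=np.float32)
    data[label] = spec.cell_intensity
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, spec.shape).astype(np.float32)
    vol = Volume3D(
        data=data,
        voxel_size_um=spec.voxel_size_um,
        mask=np.ones(spec.shape, dtype=bool),
        meta={"phantom": "cartilage", "seed": spec.seed, "layer_bounds_vox": bounds.tolist()},
    )
    return vol, label


# ---------------------------------------------------------------------------
# Standard-linear-solid loading curves
# ---------------------------------------------------------------------------


@dataclass
class SLSParams:
    """Standard-linear-solid material parameters.

    The SLS is the simplest viscoelastic model with distinct instantaneous
    (E0) and equilibrium (Einf) moduli, so parameter recovery by the
    mechanics module is analytic: a step strain eps0 relaxes as
    ``sigma(t) = eps0 * (Einf + (E0 - Einf) * exp(-t / tau))``.
    """

    E0_MPa: float = 2.0
    Einf_MPa: float = 1.0
    tau_s: float = 20.0
    noise_sd_N: float = 0.0

    def __post_init__(self) -> None:
        if not (self.E0_MPa >= self.Einf_MPa > 0):
            raise ValueError("require E0 >= Einf > 0")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")


def sls_stress_piecewise(
    t: np.ndarray, segments: list[tuple[float, float, float]], params: SLSParams
) -> np.ndarray:
    """Exact SLS stress for piecewise-linear strain, by ramp superposition.

    ``segments`` lists (start_s, stop_s, strain_rate_per_s).  The response
    to a unit-rate ramp starting at 0 is
    ``R(t) = Einf*t + (E0-Einf)*tau*(1 - exp(-t/tau))``; a ramp of rate r
    on [a, b] contributes ``r*(R(t-a) - R(max(t-b, 0)))``.
    """
    t = np.asarray(t, dtype=float)

    def R(u: np.ndarray) -> np.ndarray:
        u = np.maximum(u, 0.0)
        return params.Einf_MPa * u + (params.E0_MPa - params.Einf_MPa) * params.tau_s * (
            1.0 - np.exp(-u / params.tau_s)
        )

    sigma = np.zeros_like(t)
    for a, b, rate in segments:
        if rate != 0.0:
            sigma += rate * (R(t - a) - R(t - b))
    return sigma


def gen_loading_curve(
    protocol: ProtocolSpec,
    params: SLSParams,
    seed: int = 0,
    dt_s: float = 0.5,
    sample_height_mm: float = 2.0,
) -> LoadingRecord:
    """Simulate the rheometer force response of an SLS sample to a protocol.

    Stress follows the exact SLS solution for the protocol's piecewise-linear
    strain history and is converted to force through the 4-mm-diameter
    cross-section; Gaussian force noise of sd ``params.noise_sd_N`` is added.
    Ground-truth moduli are recorded in ``record.meta['sls_truth']``.
    """
    if any(s <= 0 for s in protocol.target_strains_pct):
        raise ValueError("strain targets must be positive")
    t, strain, segments = strain_timeline(protocol, dt_s)
    sigma = sls_stress_piecewise(t, segments, params)
    area_mm2 = np.pi * (protocol_diameter_mm(protocol) / 2.0) ** 2
    force = sigma * area_mm2  # MPa * mm^2 = N
    rng = np.random.default_rng(seed)
    if params.noise_sd_N > 0:
        force = force + rng.normal(0.0, params.noise_sd_N, force.shape)
    return LoadingRecord(
        time_s=t,
        force_N=force,
        displacement_mm=strain * sample_height_mm,
        sample_diameter_mm=protocol_diameter_mm(protocol),
        sample_height_mm=sample_height_mm,
        meta={
            "sls_truth": {
                "E0_MPa": params.E0_MPa,
                "Einf_MPa": params.Einf_MPa,
                "tau_s": params.tau_s,
            },
            "protocol": protocol.kind,
            "seed": seed,
        },
    )


def protocol_diameter_mm(protocol: ProtocolSpec) -> float:
    return getattr(protocol, "sample_diameter_mm", 4.0)


def sls_ramp_stress_closed_form(t, rate: float, params: SLSParams) -> np.ndarray:
    """Closed-form SLS stress under a single never-ending ramp (rate/s)."""
    return sls_ramp_stress(np.asarray(t, float), rate, params.E0_MPa, params.Einf_MPa, params.tau_s)


# ---------------------------------------------------------------------------
# Repeated-scan pairs
# ---------------------------------------------------------------------------


def gen_repeat_pair(
    vol: Volume3D,
    shift_vox: tuple[float, float, float] = (0, 0, 0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Volume3D, Volume3D]:
    """Emulate a remove-and-rescan pair: rigid shift + fresh noise.

    The first output is the input volume plus one noise realization; the
    second is the input rigidly translated by ``shift_vox`` (periodic
    boundary for integer shifts, spline interpolation otherwise) plus an
    independent realization.  With zero shift and zero noise the two
    volumes are identical.
    """
    shift = np.asarray(shift_vox, dtype=float)
    if np.any(np.abs(shift) >= np.asarray(vol.shape) / 2):
        raise ValueError("shift must be smaller than half the volume extent")
    rng = np.random.default_rng(seed)
    base = vol.data.astype(np.float32)
    if np.allclose(shift, np.round(shift)):
        moved = np.roll(base, np.round(shift).astype(int), axis=(0, 1, 2))
    else:
        moved = ndimage.shift(base, shift, order=3, mode="grid-wrap")
    a = base + (rng.normal(0.0, noise_sd, base.shape).astype(np.float32) if noise_sd > 0 else 0.0)
    b = moved + (rng.normal(0.0, noise_sd, base.shape).astype(np.float32) if noise_sd > 0 else 0.0)
    mk = lambda d, tag: Volume3D(
        data=d,
        voxel_size_um=vol.voxel_size_um,
        meta={**vol.meta, "repeat": tag, "true_shift_vox": tuple(shift.tolist())},
    )
    return mk(a, "scan1"), mk(b, "scan2")
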