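"""3D collagen fiber orientation by the structure gradient tensor.

The local fiber direction in a grayscale volume is the direction along
which intensity varies least.  It is found per voxel from the structure
tensor: smooth the image (Gaussian, sigma 1 voxel), take the 3D Sobel
gradient g, form the outer product g g^T, smooth each of its six unique
components (Gaussian, sigma 4 voxels), and eigendecompose the resulting
symmetric 3x3 matrix.  With eigenvalues sorted descending
(lambda1 >= lambda2 >= lambda3), the eigenvector of the *smallest*
eigenvalue points along the fiber, since gradients are weakest along it
and strongest across it.

Angle convention (fixed for the whole package): the volume axes are
(z, y, x) with z the loading/depth axis.  Azimuth phi is the in-plane
angle from +x within the x-y (cross-sectional) plane, folded to
[0, 180) degrees; elevation theta is the angle from the x-y plane toward
+z, in [-90, 90] degrees.  Orientations are axial (a fiber and its
reverse are the same), so each direction vector is first folded into the
y >= 0 hemisphere — exactly the half-sphere that the (phi, theta)
supports parameterize — before the angles are read off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_core import Volume3D, logger

#: Voxels closer than this many tensor-smoothing sigmas to the volume
#: edge are marked invalid (boundary padding contaminates the tensor).
EDGE_EXCLUSION_SIGMAS = 2.0

#: Default anisotropy (coherence) threshold for the validity mask.
DEFAULT_COHERENCE_MIN = 0.01

#: |theta| above which the azimuth is geometrically meaningless.
AZIMUTH_DEGENERACY_ELEVATION_DEG = 85.0


@dataclass
class OrientationField:
    """Per-voxel fiber orientation maps.

    ``azimuth_deg`` in [0, 180), ``elevation_deg`` in [-90, 90],
    ``coherence`` = (lambda1 - lambda3) / (lambda1 + lambda2 + lambda3)
    in [0, 1].  ``valid_mask`` excludes edge voxels and voxels with
    near-isotropic tensors; ``azimuth_valid_mask`` additionally excludes
    near-vertical fibers, whose azimuth is undefined.
    """

    azimuth_deg: np.ndarray
    elevation_deg: np.ndarray
    coherence: np.ndarray
    valid_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def azimuth_valid_mask(self) -> np.ndarray:
        return self.valid_mask & (
            np.abs(self.elevation_deg) < AZIMUTH_DEGENERACY_ELEVATION_DEG
        )


@dataclass
class OrientationHistogram:
    """Normalized angle histogram with uniform bins."""

    bin_edges_deg: np.ndarray
    counts_norm: np.ndarray
    angle_kind: str  # "azimuth" | "elevation"

    def __post_init__(self) -> None:
        if self.angle_kind not in ("azimuth", "elevation"):
            raise ValueError("angle_kind must be 'azimuth' or 'elevation'")
        total = self.counts_norm.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"normalized counts must sum to 1, got {total}")

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])

    def peak(self) -> tuple[float, float]:
        """(bin centre, height) of the histogram maximum.

        Ties are broken toward the smallest |angle| and flagged in the log.
        """
        top = self.counts_norm.max()
        tied = np.where(self.counts_norm == top)[0]
        if len(tied) > 1:
            logger.warning("OrientationHistogram.peak: %d tied maxima", len(tied))
            centers = self.bin_centers_deg[tied]
            idx = tied[np.argmin(np.abs(centers))]
        else:
            idx = tied[0]
        return float(self.bin_centers_deg[idx]), float(top)


def vectors_to_angles(vecs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axial (phi, theta) in degrees from direction vectors in (z, y, x) order.

    Vectors are folded into the y >= 0 hemisphere (ties broken toward
    x >= 0, then z > 0), so that phi = atan2(y, x) lands in [0, 180] and
    theta = asin(z / |v|) keeps its sign — the antipodal map leaves the
    stored angles unchanged.
    """
    v = np.asarray(vecs, dtype=float)
    vz, vy, vx = v[..., 0], v[..., 1], v[..., 2]
    flip = (vy < 0) | ((vy == 0) & (vx < 0)) | ((vy == 0) & (vx == 0) & (vz < 0))
    sign = np.where(flip, -1.0, 1.0)
    vz, vy, vx = vz * sign, vy * sign, vx * sign
    norm = np.sqrt(vx * vx + vy * vy + vz * vz)
    norm = np.where(norm == 0, 1.0, norm)
    phi = np.rad2deg(np.arctan2(vy, vx)) % 180.0
    theta = np.rad2deg(np.arcsin(np.clip(vz / norm, -1.0, 1.0)))
    return phi, theta


def structure_tensor_orientation(
    vol: Volume3D,
    sigma_grad_px: float = 1.0,
    sigma_tensor_px: float = 4.0,
    coherence_min: float = DEFAULT_COHERENCE_MIN,
) -> OrientationField:
    """Per-voxel fiber orientation from the structure gradient tensor.

    Pipeline: Gaussian(sigma_grad) smoothing -> 3D Sobel gradient ->
    outer-product tensor -> component-wise Gaussian(sigma_tensor)
    smoothing -> eigendecomposition; the fiber direction is the
    eigenvector of the smallest eigenvalue.  Mirror padding is used for
    both smoothing stages, and voxels within 2 sigma_tensor of the edge
    are marked invalid.  The output is invariant to positive intensity
    scaling and to intensity inversion.
    """
    data = np.asarray(vol.data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite voxels")
    if min(data.shape) <= 6 * sigma_tensor_px:
        raise ValueError(
            f"volume shape {data.shape} too small for sigma_tensor={sigma_tensor_px}"
        )

    smoothed = ndimage.gaussian_filter(data, sigma_grad_px, mode="mirror")
    grads = [ndimage.sobel(smoothed, axis=a, mode="mirror") for a in range(3)]

    # six unique tensor components, smoothed: zz, zy, zx, yy, yx, xx
    pairs = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    comps = [
        ndimage.gaussian_filter(grads[a] * grads[b], sigma_tensor_px, mode="mirror")
        for a, b in pairs
    ]
    tensor = np.empty(data.shape + (3, 3), dtype=np.float32)
    for (a, b), c in zip(pairs, comps):
        tensor[..., a, b] = c
        tensor[..., b, a] = c

    evals, evecs = np.linalg.eigh(tensor.reshape(-1, 3, 3))  # ascending eigenvalues
    trace = evals.sum(axis=1)
    lam1, lam3 = evals[:, 2], evals[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(trace > 0, (lam1 - lam3) / np.where(trace > 0, trace, 1.0), 0.0)
    fiber_vecs = evecs[:, :, 0]  # eigenvector of the smallest eigenvalue, (z, y, x)

    phi, theta = vectors_to_angles(fiber_vecs)
    shape = data.shape
    coherence = coherence.reshape(shape).astype(np.float32)

    valid = coherence >= coherence_min
    margin = int(np.ceil(EDGE_EXCLUSION_SIGMAS * sigma_tensor_px))
    edge = np.zeros(shape, dtype=bool)
    if margin > 0:
        core = tuple(slice(margin, s - margin) for s in shape)
        edge[:] = True
        edge[core] = False
    valid &= ~edge

    return OrientationField(
        azimuth_deg=phi.reshape(shape).astype(np.float32),
        elevation_deg=theta.reshape(shape).astype(np.float32),
        coherence=coherence,
        valid_mask=valid,
        meta={
            "sigma_grad_px": sigma_grad_px,
            "sigma_tensor_px": sigma_tensor_px,
            "coherence_min": coherence_min,
            "edge_margin_px": margin,
        },
    )


def orientation_histograms(
    field: OrientationField,
    mask: np.ndarray | None = None,
    bin_deg: float = 1.0,
    coherence_weighted: bool = False,
) -> tuple[OrientationHistogram, OrientationHistogram]:
    """Azimuth and elevation histograms over masked valid voxels.

    Counts are normalized to sum to 1.  The azimuth histogram uses the
    stricter azimuth-validity mask (near-vertical fibers excluded); with
    ``coherence_weighted`` voxels contribute their coherence instead of 1.
    """
    base = field.valid_mask if mask is None else (field.valid_mask & np.asarray(mask, bool))
    az_sel = base & field.azimuth_valid_mask
    if not base.any() or not az_sel.any():
        raise ValueError("no valid voxels under the supplied mask")

    def _hist(values: np.ndarray, sel: np.ndarray, lo: float, hi: float, kind: str):
        edges = np.arange(lo, hi + bin_deg / 2, bin_deg)
        weights = field.coherence[sel] if coherence_weighted else None
        counts, _ = np.histogram(values[sel], bins=edges, weights=weights)
        total = counts.sum()
        if total == 0:
            raise ValueError(f"empty {kind} histogram")
        return OrientationHistogram(edges, counts / total, kind)

    az = _hist(field.azimuth_deg, az_sel, 0.0, 180.0, "azimuth")
    el = _hist(field.elevation_deg, base, -90.0, 90.0, "elevation")
    return az, el


def average_histograms(hists: list[OrientationHistogram]) -> OrientationHistogram:
    """Average identically binned normalized histograms (e.g. 5 subvolumes)."""
    if not hists:
        raise ValueError("no histograms to average")
    edges = hists[0].bin_edges_deg
    kind = hists[0].angle_kind
    for h in hists[1:]:
        if h.angle_kind != kind or not np.array_equal(h.bin_edges_deg, edges):
            raise ValueError("histograms must share binning and angle kind")
    mean = np.mean([h.counts_norm for h in hists], axis=0)
    return OrientationHistogram(edges, mean / mean.sum(), kind)


def track_peak_height(
    histograms_by_timepoint: dict,
) -> list[tuple[object, float, float]]:
    """Peak angle and height of one histogram per time point.

    Input maps an orderable time-point label to an
    :class:`OrientationHistogram`; all must be identically binned.
    Returns ``[(timepoint, peak_angle_deg, peak_height), ...]`` ordered
    by time point.
    """
    if len(histograms_by_timepoint) < 1:
        raise ValueError("need at least one time point")
    items = sorted(histograms_by_timepoint.items(), key=lambda kv: kv[0])
    ref = items[0][1]
    out = []
    for tp, hist in items:
        if not np.array_equal(hist.bin_edges_deg, ref.bin_edges_deg):
            raise ValueError("histograms must be identically binned across time points")
        angle, height = hist.peak()
        out.append((tp, angle, height))
    return out
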