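"""Volume and loading-table I/O, subvolume cropping, shared domain types.

Conventions used throughout the package
---------------------------------------
* Volumes are indexed ``(z, y, x)`` with ``z`` the loading / tissue-depth
  axis.  Indices are 0-based and ranges are half-open.
* Physical sizes are given in micrometres; the default voxel size is
  2.75 um, the acquisition pixel size of the synchrotron setup the
  pipeline targets.
* Intensities are kept as stored.  Any normalization applied on read is
  explicit and recorded, because SNR is not offset-invariant.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("situtomo")

#: Acquisition pixel size of the targeted setup, micrometres per voxel.
DEFAULT_VOXEL_SIZE_UM = 2.75

#: Lateral side of the standard analysis subvolume, micrometres.
DEFAULT_SUBVOLUME_LATERAL_UM = 500.0

#: Standard number of analysis subvolumes cropped per tomogram.
DEFAULT_SUBVOLUME_COUNT = 5


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a stream handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(name)s %(levelname)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


def load_config(path: str | Path) -> dict:
    """Load a YAML key/value configuration file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    return cfg


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Volume3D:
    """A 3D grayscale volume with physical voxel size.

    Parameters
    ----------
    data:
        3D array ordered ``(z, y, x)``; ``z`` is the loading/depth axis.
    voxel_size_um:
        Isotropic voxel size in micrometres (> 0).
    mask:
        Optional boolean tissue mask of identical shape.
    meta:
        Free-form provenance/metadata dictionary.
    """

    data: np.ndarray
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D data must be 3D, got ndim={self.data.ndim}")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape:
                raise ValueError("mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def um_to_vox(self, size_um: float) -> int:
        """Convert a physical size to a voxel count (nearest integer)."""
        return int(round(size_um / self.voxel_size_um))


@dataclass
class SubvolumeSet:
    """Cropped analysis subvolumes plus their source regions.

    ``regions`` are triples of half-open ``(start, stop)`` voxel intervals
    in ``(z, y, x)`` order, all fully inside the parent volume.
    """

    parent_id: str
    regions: list[tuple[tuple[int, int], tuple[int, int], tuple[int, int]]]
    volumes: list[Volume3D]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.volumes)

    def __iter__(self):
        return iter(self.volumes)


@dataclass
class LoadingRecord:
    """Time-resolved force/displacement data from the rheometer.

    Stress and strain are filled in by :func:`situtomo.mechanics.to_stress_strain`;
    compression is reported as positive magnitudes.  Strain is expressed as a
    fraction of the post-preload sample height.
    """

    time_s: np.ndarray
    force_N: np.ndarray
    displacement_mm: np.ndarray
    sample_diameter_mm: float = 4.0
    sample_height_mm: float | None = None
    stress_MPa: np.ndarray | None = None
    strain_frac: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        n = len(self.time_s)
        if len(self.force_N) != n or len(self.displacement_mm) != n:
            raise ValueError("time, force and displacement must have equal length")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("time series must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------


def _natural_key(name: str) -> list:
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name)]


def read_volume_stack(
    path: str | Path,
    voxel_size_um: float = DEFAULT_VOXEL_SIZE_UM,
    rescale: bool = False,
) -> Volume3D:
    """Read a TIFF stack (directory of slices or one multipage file) into a volume.

    Slices from a directory are stacked along ``z`` in natural filename order.
    With ``rescale=True`` intensities are mapped linearly to [0, 1] and the
    affine transform is recorded in ``meta['rescale']``.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")],
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise FileNotFoundError(f"no TIFF slices found in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1 or slices[0].ndim != 2:
            raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        data = np.stack(slices, axis=0)
    elif path.is_file():
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"{path} does not contain a 2D/3D image (ndim={data.ndim})")
    else:
        raise FileNotFoundError(f"{path} does not exist")

    meta: dict = {"source": str(path)}
    if rescale:
        lo, hi = float(data.min()), float(data.max())
        scale = hi - lo if hi > lo else 1.0
        data = (data.astype(np.float32) - lo) / scale
        meta["rescale"] = {"offset": lo, "scale": scale}
    return Volume3D(data=data, voxel_size_um=voxel_size_um, meta=meta)


def write_volume_stack(vol: Volume3D, path: str | Path) -> Path:
    """Write a volume as a multipage TIFF; the round-trip is lossless."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = vol.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    elif data.dtype == bool:
        data = data.astype(np.uint8)
    tifffile.imwrite(path, data)
    return path


# ---------------------------------------------------------------------------
# Loading-table I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMN_MAP = {
    "time_s": "time_s",
    "force_N": "force_N",
    "displacement_mm": "displacement_mm",
}


def read_loading_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    sample_diameter_mm: float = 4.0,
    sample_height_mm: float | None = None,
) -> LoadingRecord:
    """Read a delimited rheometer export into a :class:`LoadingRecord`.

    ``column_map`` maps record fields (``time_s``, ``force_N``,
    ``displacement_mm``) to column names in the file.  Rows containing
    non-finite entries in any mapped column are dropped and counted in the
    log.  The delimiter is sniffed by pandas when ``sep`` is None.
    """
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [col for col in cmap.values() if col not in df.columns]
    if missing:
        raise KeyError(f"missing mapped column(s) {missing} in {path}; have {list(df.columns)}")
    sub = df[[cmap["time_s"], cmap["force_N"], cmap["displacement_mm"]]].astype(float)
    finite = np.isfinite(sub.to_numpy()).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        logger.warning("read_loading_table: dropped %d non-finite row(s) from %s", dropped, path)
    sub = sub[finite]
    return LoadingRecord(
        time_s=sub[cmap["time_s"]].to_numpy(),
        force_N=sub[cmap["force_N"]].to_numpy(),
        displacement_mm=sub[cmap["displacement_mm"]].to_numpy(),
        sample_diameter_mm=sample_diameter_mm,
        sample_height_mm=sample_height_mm,
        meta={"source": str(path), "dropped_rows": dropped},
    )


# ---------------------------------------------------------------------------
# Subvolume cropping
# ---------------------------------------------------------------------------


def crop_full_depth_subvolumes(
    vol: Volume3D,
    lateral_size_um: float = DEFAULT_SUBVOLUME_LATERAL_UM,
    count: int = DEFAULT_SUBVOLUME_COUNT,
    seed: int = 0,
    max_tries: int = 10_000,
) -> SubvolumeSet:
    """Crop ``count`` full-depth lateral subvolumes at seed-fixed random positions.

    The lateral side in voxels is the nearest integer to
    ``lateral_size_um / voxel_size_um`` (500 um -> 182 voxels at 2.75 um).
    Regions span the full z extent and are placed by uniform rejection
    sampling; non-overlapping placement is attempted first and relaxed
    (with a warning) only when infeasible within the retry budget.  When the
    volume carries a tissue mask, candidate footprints must lie at least 80%
    inside the mask's lateral projection.
    """
    nz, ny, nx = vol.shape
    side = vol.um_to_vox(lateral_size_um)
    if side > ny or side > nx:
        raise ValueError(
            f"lateral size {lateral_size_um} um = {side} vox exceeds volume extent ({ny}, {nx})"
        )
    rng = np.random.default_rng(seed)

    lateral_mask = None
    if vol.mask is not None:
        lateral_mask = vol.mask.any(axis=0)

    def _acceptable(y0: int, x0: int) -> bool:
        if lateral_mask is None:
            return True
        footprint = lateral_mask[y0 : y0 + side, x0 : x0 + side]
        return footprint.mean() >= 0.8

    def _overlaps(y0: int, x0: int, placed: list[tuple[int, int]]) -> bool:
        return any(abs(y0 - py) < side and abs(x0 - px) < side for py, px in placed)

    placed: list[tuple[int, int]] = []
    allow_overlap = False
    tries = 0
    while len(placed) < count:
        if tries >= max_tries:
            if allow_overlap:
                raise RuntimeError(
                    f"could not place {count} subvolumes of side {side} vox even with overlap"
                )
            allow_overlap = True
            tries = 0
            logger.warning(
                "crop_full_depth_subvolumes: cannot place %d non-overlapping %dx%d regions; "
                "falling back to overlapping placement",
                count,
                side,
                side,
            )
            continue
        tries += 1
        y0 = int(rng.integers(0, ny - side + 1))
        x0 = int(rng.integers(0, nx - side + 1))
        if not _acceptable(y0, x0):
            continue
        if not allow_overlap and _overlaps(y0, x0, placed):
            continue
        placed.append((y0, x0))

    regions = [((0, nz), (y0, y0 + side), (x0, x0 + side)) for y0, x0 in placed]
    volumes = []
    for (z0, z1), (y0, y1), (x0, x1) in regions:
        sub_mask = vol.mask[z0:z1, y0:y1, x0:x1] if vol.mask is not None else None
        volumes.append(
            Volume3D(
                data=vol.data[z0:z1, y0:y1, x0:x1],
                voxel_size_um=vol.voxel_size_um,
                mask=sub_mask,
                meta={"region": ((z0, z1), (y0, y1), (x0, x1))},
            )
        )
    return SubvolumeSet(
        parent_id=str(vol.meta.get("source", "volume")),
        regions=regions,
        volumes=volumes,
        meta={
            "lateral_size_um": lateral_size_um,
            "lateral_size_vox": side,
            "seed": seed,
            "overlap_fallback": allow_overlap,
        },
    )
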