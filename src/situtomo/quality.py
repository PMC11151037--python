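"""Image-quality metrics: Fourier-criterion resolution, SNR and CNR.

Spatial resolution follows a power-spectral-density criterion: the
rotationally averaged PSD of a band-limited image falls to the flat
noise baseline at a cutoff frequency f_c, and 1/f_c (in voxels) is taken
as the spatial resolution.  The baseline is estimated as the mean power
over the highest frequencies, and the cutoff as the lowest frequency
beyond which the power stays below a small factor times that baseline.

SNR is the mean foreground intensity over the background standard
deviation; CNR between features A and B is

    CNR = (I_A - I_B) / sqrt((sigma_A^2 + sigma_B^2) / 2)

Both ratios are invariant to multiplying the volume by a positive
constant.  CNR is additionally invariant to adding a constant offset;
SNR is not, since the offset moves the foreground mean but not the
background spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import Volume3D, logger


@dataclass
class QualityReport:
    """Aggregated image-quality metrics of one volume."""

    resolution_px: float
    resolution_um: float
    snr: float | None = None
    cnr_pairs: dict = field(default_factory=dict)
    baseline_power: float | None = None
    cutoff_freq_cyc_per_px: float | None = None
    degenerate: bool = False


def radial_psd(
    vol: Volume3D | np.ndarray, n_bins: int = 64, per_slice: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Rotationally averaged power spectral density up to Nyquist.

    The mean is removed before the transform.  Frequencies are in
    cycles/voxel; power is averaged over spherical shells of frequency
    magnitude (circular annuli per z-slice, then averaged, when
    ``per_slice`` is set).  Returns ``(bin_centers, mean_power)``.
    """
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    data = data.astype(float) - data.mean()
    if per_slice:
        power = np.mean([np.abs(np.fft.fftn(sl)) ** 2 for sl in data], axis=0)
        freqs = np.meshgrid(*[np.fft.fftfreq(s) for s in data.shape[1:]], indexing="ij")
    else:
        power = np.abs(np.fft.fftn(data)) ** 2
        freqs = np.meshgrid(*[np.fft.fftfreq(s) for s in data.shape], indexing="ij")
    fmag = np.sqrt(sum(f * f for f in freqs))
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    which = np.digitize(fmag.ravel(), edges) - 1
    keep = (which >= 0) & (which < n_bins)
    counts = np.bincount(which[keep], minlength=n_bins)
    sums = np.bincount(which[keep], weights=power.ravel()[keep], minlength=n_bins)
    mean_power = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    if np.all(mean_power == 0):
        logger.warning("radial_psd: constant image, all-zero spectrum")
    return centers, mean_power


def estimate_resolution(
    psd: tuple[np.ndarray, np.ndarray],
    baseline_fraction: float = 0.1,
    threshold_factor: float = 1.1,
) -> tuple[float, dict]:
    """Spatial resolution (voxels) from a radial PSD by baseline crossing.

    baseline = mean power over the top ``baseline_fraction`` of frequency
    bins; cutoff f_c = lowest frequency beyond which the power stays
    below ``threshold_factor * baseline`` for all higher bins;
    resolution = 1/f_c.  A spectrum at baseline everywhere (pure noise,
    no resolved band) is flagged degenerate, with the resolution reported
    as the largest measurable scale (1 / first bin).

    Returns ``(resolution_px, info)`` where info carries the baseline,
    cutoff and degeneracy flag.
    """
    freqs, power = np.asarray(psd[0]), np.asarray(psd[1])
    if len(freqs) < 16:
        raise ValueError("need at least 16 PSD bins")
    n_base = max(1, int(round(baseline_fraction * len(freqs))))
    baseline = float(power[-n_base:].mean())
    thresh = threshold_factor * baseline
    # single noise bins fluctuate by a few percent; judge convergence on a
    # 3-bin forward moving average so one outlier bin cannot postpone the
    # cutoff, while the cutoff itself keeps single-bin resolution
    w = min(3, len(power))
    padded = np.concatenate([power, np.full(w - 1, baseline)])
    fwd_mean = np.convolve(padded, np.ones(w) / w, mode="valid")
    below = fwd_mean < thresh
    # lowest frequency from which everything above stays below threshold
    stays = np.logical_and.accumulate(below[::-1])[::-1]
    idx = int(np.argmax(stays)) if stays.any() else None
    info = {"baseline_power": baseline, "degenerate": False}
    # a genuine signal band must clear the baseline decisively below the cutoff
    if idx is not None and idx > 0 and baseline > 0 and power[:idx].max() < 5.0 * baseline:
        idx = 0
    if idx is None or idx == 0:
        # never converges, or already at baseline from the start
        info["degenerate"] = True
        info["cutoff_freq_cyc_per_px"] = float(freqs[0])
        resolution = 1.0 / float(freqs[0])
        logger.warning("estimate_resolution: degenerate spectrum (no resolved band)")
        return resolution, info
    f_c = float(freqs[idx])
    info["cutoff_freq_cyc_per_px"] = f_c
    return 1.0 / f_c, info


def compute_snr(vol: Volume3D | np.ndarray, fg_mask: np.ndarray, bg_mask: np.ndarray) -> float:
    """Signal-to-noise ratio: mean(foreground) / sd(background, ddof=1)."""
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol)
    fg_mask = np.asarray(fg_mask, dtype=bool)
    bg_mask = np.asarray(bg_mask, dtype=bool)
    if not fg_mask.any() or not bg_mask.any():
        raise ValueError("foreground and background masks must be non-empty")
    if np.any(fg_mask & bg_mask):
        raise ValueError("foreground and background masks must be disjoint")
    sd = float(np.std(data[bg_mask], ddof=1))
    if sd == 0.0:
        logger.warning("compute_snr: zero background sd, SNR undefined (inf)")
        return float("inf")
    return float(np.mean(data[fg_mask]) / sd)


def compute_cnr(vol: Volume3D | np.ndarray, maskA: np.ndarray, maskB: np.ndarray) -> float:
    """Contrast-to-noise ratio between features A and B.

    (I_A - I_B) / sqrt((sigma_A^2 + sigma_B^2)/2), antisymmetric in its
    arguments.
    """
    data = vol.data if isinstance(vol, Volume3D) else np.asarray(vol)
    maskA = np.asarray(maskA, dtype=bool)
    maskB = np.asarray(maskB, dtype=bool)
    if not maskA.any() or not maskB.any():
        raise ValueError("both masks must be non-empty")
    if np.any(maskA & maskB):
        raise ValueError("masks must be disjoint")
    a, b = data[maskA], data[maskB]
    denom = np.sqrt(0.5 * (np.var(a, ddof=1) + np.var(b, ddof=1)))
    if denom == 0.0:
        logger.warning("compute_cnr: both feature sds are zero, CNR undefined (inf)")
        return float("inf") if a.mean() > b.mean() else float("-inf")
    return float((a.mean() - b.mean()) / denom)


def quality_report(
    vol: Volume3D,
    fg_mask: np.ndarray | None = None,
    bg_mask: np.ndarray | None = None,
    cnr_masks: dict | None = None,
    baseline_fraction: float = 0.1,
    threshold_factor: float = 1.1,
) -> QualityReport:
    """One-stop report: resolution plus optional SNR and CNR pairs.

    ``cnr_masks`` maps pair labels (e.g. ``("matrix", "cells")``) to
    ``(maskA, maskB)`` tuples.
    """
    psd = radial_psd(vol)
    res_px, info = estimate_resolution(psd, baseline_fraction, threshold_factor)
    report = QualityReport(
        resolution_px=res_px,
        resolution_um=res_px * vol.voxel_size_um,
        baseline_power=info["baseline_power"],
        cutoff_freq_cyc_per_px=info.get("cutoff_freq_cyc_per_px"),
        degenerate=info["degenerate"],
    )
    if fg_mask is not None and bg_mask is not None:
        report.snr = compute_snr(vol, fg_mask, bg_mask)
    for label, (mA, mB) in (cnr_masks or {}).items():
        report.cnr_pairs[label] = compute_cnr(vol, mA, mB)
    return report
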