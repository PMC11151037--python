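"""Mechanical analysis of unconfined compression tests, plus dose estimation.

Covers the two loading protocols used for in situ imaging —

* **Continuous loading (CL)**: after a 2 N preload, a constant strain rate
  of 0.03 %/s up to 15 % (cartilage) or 30 % (meniscus) strain, with seven
  tomographic scans spaced equidistantly along the ramp.
* **Stress-relaxation (StR)**: two 15 % strain steps at 1 %/s ramp speed,
  held for 600 s and 900 s, with scans at each compression peak and at
  fixed relaxation offsets (20, 40, 60, 100, 300, 600 s).

and the derived quantities: stress/strain conversion at a fixed 4 mm
sample diameter, instantaneous modulus E_i (stress-strain slope at each
load step), quasi-equilibrium modulus E_qeq (slope between fully relaxed
stresses at successive strains), relaxation ratios, equilibrium Poisson's
ratio from lateral widening measured on the volumes, the aggregate
modulus H_A = (1-nu) E_qeq / ((1+nu)(1-2nu)), and the mean absorbed dose
of a uniformly illuminated rotating soft-tissue cylinder.

Compression sign convention: strains and stresses are reported as
positive magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import integrate

from .io_core import LoadingRecord, Volume3D, logger

#: Mass attenuation coefficient of soft tissue at 21 keV, cm^2/g.
SOFT_TISSUE_MU_OVER_RHO_CM2_G = 0.7786

#: Assumed soft-tissue density, g/cm^3.
SOFT_TISSUE_DENSITY_G_CM3 = 1.06


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------


@dataclass
class ProtocolSpec:
    """Parameters of a compression protocol and its scan plan.

    ``kind`` is "CL" or "StR".  Strain values are in percent; the strain
    reference is the post-preload sample height.  For CL, ``n_scans``
    equidistant scans cover the ramp; for StR, scans fire at each peak
    plus each entry of ``scan_offsets_s`` after the peak (offset 0 is the
    peak itself).
    """

    kind: str
    preload_N: float = 2.0
    strain_rate_pct_per_s: float = 0.03
    target_strains_pct: tuple[float, ...] = (15.0,)
    relaxation_s: tuple[float, ...] = ()
    n_scans: int = 7
    scan_offsets_s: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 100.0, 300.0, 600.0)
    sample_diameter_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("CL", "StR"):
            raise ValueError("protocol kind must be 'CL' or 'StR'")
        if list(self.target_strains_pct) != sorted(self.target_strains_pct):
            raise ValueError("target strains must be increasing")
        if any(r <= 0 for r in self.relaxation_s):
            raise ValueError("relaxation times must be positive")
        if list(self.scan_offsets_s) != sorted(self.scan_offsets_s):
            raise ValueError("scan offsets must be sorted")
        if self.kind == "StR" and len(self.relaxation_s) != len(self.target_strains_pct):
            raise ValueError("StR needs one relaxation time per strain step")

    @classmethod
    def continuous_loading(cls, target_strain_pct: float = 15.0,
                           rate_pct_per_s: float = 0.03, n_scans: int = 7) -> "ProtocolSpec":
        return cls(kind="CL", strain_rate_pct_per_s=rate_pct_per_s,
                   target_strains_pct=(target_strain_pct,), n_scans=n_scans)

    @classmethod
    def stress_relaxation(cls, target_strains_pct: Sequence[float] = (15.0, 30.0),
                          ramp_rate_pct_per_s: float = 1.0,
                          relaxation_s: Sequence[float] = (600.0, 900.0)) -> "ProtocolSpec":
        return cls(kind="StR", strain_rate_pct_per_s=ramp_rate_pct_per_s,
                   target_strains_pct=tuple(target_strains_pct),
                   relaxation_s=tuple(relaxation_s))

    @property
    def duration_s(self) -> float:
        rate = self.strain_rate_pct_per_s
        if self.kind == "CL":
            return self.target_strains_pct[-1] / rate
        total, prev = 0.0, 0.0
        for target, relax in zip(self.target_strains_pct, self.relaxation_s):
            total += (target - prev) / rate + relax
            prev = target
        return total


def strain_timeline(
    protocol: ProtocolSpec, dt_s: float = 0.5
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float, float]]]:
    """Sampled strain history (as a fraction) and its ramp segments.

    Returns ``(t, strain, segments)`` where each segment is
    ``(start_s, stop_s, strain_rate_per_s)`` with rate in fraction/s.
    """
    rate_frac = protocol.strain_rate_pct_per_s / 100.0
    segments: list[tuple[float, float, float]] = []
    t0, prev_frac = 0.0, 0.0
    if protocol.kind == "CL":
        T = protocol.duration_s
        segments.append((0.0, T, rate_frac))
    else:
        for target, relax in zip(protocol.target_strains_pct, protocol.relaxation_s):
            target_frac = target / 100.0
            ramp = (target_frac - prev_frac) / rate_frac
            segments.append((t0, t0 + ramp, rate_frac))
            t0 += ramp + relax
            prev_frac = target_frac
        T = t0
    t = np.arange(0.0, T + dt_s / 2, dt_s)
    strain = np.zeros_like(t)
    for a, b, r in segments:
        strain += r * (np.clip(t, a, b) - a)
    return t, strain, segments


def sls_ramp_stress(t, rate_per_s: float, E0_MPa: float, Einf_MPa: float,
                    tau_s: float) -> np.ndarray:
    """Standard-linear-solid stress under a constant-rate ramp from t=0.

    sigma(t) = r [Einf t + (E0 - Einf) tau (1 - exp(-t/tau))].
    """
    t = np.asarray(t, dtype=float)
    return rate_per_s * (Einf_MPa * t + (E0_MPa - Einf_MPa) * tau_s * (1 - np.exp(-t / tau_s)))


# ---------------------------------------------------------------------------
# Stress-strain conversion and moduli
# ---------------------------------------------------------------------------


def to_stress_strain(rec: LoadingRecord) -> LoadingRecord:
    """Fill stress (MPa) and strain (fraction) on the record, in place.

    Stress assumes a constant circular cross-section of the configured
    sample diameter; strain is displacement over the post-preload height.
    Compression is reported with positive sign.
    """
    if rec.sample_height_mm is None or rec.sample_height_mm <= 0:
        raise ValueError("sample_height_mm must be set and positive")
    area_mm2 = np.pi * (rec.sample_diameter_mm / 2.0) ** 2
    rec.stress_MPa = np.abs(rec.force_N) / area_mm2  # N / mm^2 = MPa
    rec.strain_frac = np.abs(rec.displacement_mm) / rec.sample_height_mm
    if np.any(rec.strain_frac >= 1.0):
        raise ValueError("strain magnitude >= 100%: check height/displacement units")
    return rec


def _require_stress_strain(rec: LoadingRecord) -> None:
    if rec.stress_MPa is None or rec.strain_frac is None:
        raise ValueError("record has no stress/strain: call to_stress_strain first")


def _find_steps(rec: LoadingRecord, tol: float = 1e-9) -> list[dict]:
    """Locate load steps: index of each ramp peak and its hold interval.

    A peak is a sample where strain stops increasing; the hold runs until
    strain changes again or the record ends.  A ramp still rising at the
    final sample (CL) yields a peak with an empty hold.
    """
    _require_stress_strain(rec)
    eps = np.asarray(rec.strain_frac)
    d = np.diff(eps)
    steps = []
    i = 0
    n = len(eps)
    while i < n - 1:
        if d[i] > tol:  # climbing a ramp
            j = i
            while j < n - 1 and d[j] > tol:
                j += 1
            k = j  # j is the peak index
            while k < n - 1 and abs(d[k]) <= tol:
                k += 1
            steps.append({"peak_idx": j, "hold_idx": (j, k if k > j else j)})
            i = k if k > j else j + 1
        else:
            i += 1
    return steps


def instantaneous_modulus(
    rec: LoadingRecord, step_window_strain_pct: float = 2.0
) -> np.ndarray:
    """Instantaneous modulus E_i at each load step (MPa).

    Least-squares slope of stress vs strain over the final
    ``step_window_strain_pct`` percent of strain of the ramp leading to
    each peak.
    """
    _require_stress_strain(rec)
    steps = _find_steps(rec)
    if not steps:
        raise ValueError("no load steps found in record")
    eps = np.asarray(rec.strain_frac)
    sig = np.asarray(rec.stress_MPa)
    window = step_window_strain_pct / 100.0
    out = []
    prev_end = 0
    for step in steps:
        j = step["peak_idx"]
        lo = eps[j] - window
        sel = np.arange(prev_end, j + 1)
        sel = sel[eps[sel] >= lo - 1e-12]
        if len(sel) < 3:
            raise ValueError(
                f"only {len(sel)} samples in the {step_window_strain_pct}% window before peak"
            )
        slope = np.polyfit(eps[sel], sig[sel], 1)[0]
        out.append(slope)
        prev_end = step["hold_idx"][1]
    return np.asarray(out)


def quasi_equilibrium_modulus(
    rec: LoadingRecord, eq_window_s: float = 10.0
) -> tuple[np.ndarray, float]:
    """Equilibrium stresses and the quasi-equilibrium modulus E_qeq (MPa).

    For a stress-relaxation record with (at least) two completed holds:
    the equilibrium stress of each step is the mean stress over the last
    ``eq_window_s`` seconds of its hold, and E_qeq is the slope between
    the relaxed stresses at the two step strains.  Termed *quasi*-
    equilibrium because full relaxation of meniscus can take far longer
    than the holds.
    """
    _require_stress_strain(rec)
    steps = [s for s in _find_steps(rec) if s["hold_idx"][1] > s["hold_idx"][0] + 1]
    if len(steps) < 2:
        raise ValueError("quasi-equilibrium modulus needs >= 2 completed relaxation steps")
    t = rec.time_s
    eps = np.asarray(rec.strain_frac)
    sig = np.asarray(rec.stress_MPa)
    eq_stress, eq_strain = [], []
    for step in steps:
        j, k = step["hold_idx"]
        t_end = t[k]
        sel = np.arange(j, k + 1)
        sel = sel[t[sel] >= t_end - eq_window_s]
        eq_stress.append(float(np.mean(sig[sel])))
        eq_strain.append(float(eps[j]))
    eq_stress_arr = np.asarray(eq_stress)
    e_qeq = (eq_stress_arr[-1] - eq_stress_arr[0]) / (eq_strain[-1] - eq_strain[0])
    return eq_stress_arr, float(e_qeq)


def relaxation_ratio(peak_stress: float, eq_stress: float) -> float:
    """Equilibrium-to-peak stress ratio of one relaxation step."""
    if peak_stress <= 0:
        raise ValueError("peak stress must be positive")
    ratio = eq_stress / peak_stress
    if ratio > 1.0:
        logger.warning("relaxation_ratio > 1 (%.3f): non-physical for relaxation", ratio)
    return float(ratio)


def peak_stresses(rec: LoadingRecord) -> np.ndarray:
    """Stress at each detected load-step peak (MPa)."""
    _require_stress_strain(rec)
    sig = np.asarray(rec.stress_MPa)
    return np.asarray([sig[s["peak_idx"]] for s in _find_steps(rec)])


# ---------------------------------------------------------------------------
# Poisson's ratio from volume edge profiles
# ---------------------------------------------------------------------------


def measure_sample_diameter_vox(vol: Volume3D, axis: int = 1) -> float:
    """Sample diameter along one lateral axis, in voxels, by edge profiles.

    The volume is averaged along the other two axes into a 1D intensity
    profile; the diameter is the distance between the two half-maximum
    crossings, located with linear sub-voxel interpolation.  Assumes a
    bright sample on a darker background filling the centre of the field.
    """
    if axis not in (1, 2):
        raise ValueError("axis must be 1 (y) or 2 (x)")
    other = tuple(a for a in range(3) if a != axis)
    profile = vol.data.mean(axis=other).astype(float)
    lo = profile.min()
    hi = profile.max()
    if hi <= lo:
        raise ValueError("flat profile: cannot locate sample edges")
    half = (hi + lo) / 2.0
    above = profile >= half
    idx = np.where(above)[0]
    if len(idx) == 0:
        raise ValueError("no voxels above half-maximum")
    i0, i1 = idx[0], idx[-1]

    def _cross(i_out: int, i_in: int) -> float:
        if i_out < 0 or i_out >= len(profile):
            return float(i_in)
        p_out, p_in = profile[i_out], profile[i_in]
        frac = (half - p_out) / (p_in - p_out)
        return i_out + frac * (i_in - i_out)

    left = _cross(i0 - 1, i0)
    right = _cross(i1 + 1, i1)
    return float(right - left)


def lateral_strain_from_volumes(ref: Volume3D, deformed: Volume3D) -> float:
    """Relative diameter change between two volumes, averaged over y and x."""
    strains = []
    for axis in (1, 2):
        d0 = measure_sample_diameter_vox(ref, axis)
        d1 = measure_sample_diameter_vox(deformed, axis)
        strains.append((d1 - d0) / d0)
    return float(np.mean(strains))


def poisson_ratio(lateral_strain, axial_strain) -> float:
    """Equilibrium Poisson's ratio nu_s = |lateral| / |axial| strain.

    Accepts scalars or equal-length sequences of paired measurements,
    which are averaged.  Values outside [0, 0.5) are flagged in the log
    but returned as computed.
    """
    lat = np.atleast_1d(np.asarray(lateral_strain, dtype=float))
    ax = np.atleast_1d(np.asarray(axial_strain, dtype=float))
    if np.any(ax <= 0):
        raise ValueError("axial strain must be positive")
    nu = float(np.mean(np.abs(lat) / np.abs(ax)))
    if not (0.0 <= nu < 0.5):
        logger.warning("poisson_ratio %.3f outside [0, 0.5)", nu)
    return nu


def aggregate_modulus(E_qeq_MPa: float, nu_s: float) -> float:
    """Aggregate modulus H_A = (1-nu) E / ((1+nu)(1-2nu)) (MPa).

    The confined-compression stiffness implied by the equilibrium Young's
    modulus and Poisson's ratio; diverges as nu -> 0.5 (incompressible).
    """
    if not (0.0 <= nu_s < 0.5):
        raise ValueError("nu_s must lie in [0, 0.5)")
    return float((1 - nu_s) * E_qeq_MPa / ((1 + nu_s) * (1 - 2 * nu_s)))


@dataclass
class MechanicalSummary:
    """Derived mechanical quantities of one loading experiment."""

    E_i_MPa: np.ndarray | None
    E_qeq_MPa: float | None = None
    relax_ratio: np.ndarray | None = None
    nu_s: float | None = None
    H_A_MPa: float | None = None


def summarize_mechanics(
    rec: LoadingRecord,
    nu_s: float | None = None,
    step_window_strain_pct: float = 2.0,
    eq_window_s: float = 10.0,
) -> MechanicalSummary:
    """Compute all mechanical quantities a record supports.

    CL records yield only E_i; StR records additionally yield E_qeq and
    relaxation ratios, and — when a Poisson's ratio is supplied — H_A.
    """
    _require_stress_strain(rec)
    try:
        e_i = instantaneous_modulus(rec, step_window_strain_pct)
    except ValueError as exc:  # e.g. ramps too sparsely sampled for the fit window
        logger.warning("summarize_mechanics: E_i unavailable (%s)", exc)
        e_i = None
    summary = MechanicalSummary(E_i_MPa=e_i, nu_s=nu_s)
    try:
        eq_stress, e_qeq = quasi_equilibrium_modulus(rec, eq_window_s)
    except ValueError:
        return summary
    peaks = peak_stresses(rec)
    summary.E_qeq_MPa = e_qeq
    summary.relax_ratio = np.asarray(
        [relaxation_ratio(p, e) for p, e in zip(peaks, eq_stress)]
    )
    if nu_s is not None:
        summary.H_A_MPa = aggregate_modulus(e_qeq, nu_s)
    return summary


# ---------------------------------------------------------------------------
# Absorbed dose
# ---------------------------------------------------------------------------


def absorbed_dose_cylinder(
    energy_fluence_J_per_m2: float,
    mu_over_rho_cm2_per_g: float = SOFT_TISSUE_MU_OVER_RHO_CM2_G,
    density_g_per_cm3: float = SOFT_TISSUE_DENSITY_G_CM3,
    radius_mm: float = 2.0,
) -> float:
    """Mean absorbed dose (Gy) of a uniformly illuminated rotating cylinder.

    The sample is a homogeneous soft-tissue cylinder of radius R seen
    side-on by a parallel beam covering the full cross-section; rotation
    averages the deposition azimuthally, so the mean dose is the
    Beer-Lambert chord average

        D = Psi * Int_{-R}^{R} (1 - exp(-mu 2 sqrt(R^2-x^2))) dx / (rho pi R^2)

    with mu = (mu/rho) * rho.  The dose is bounded above by both the
    optically thin limit Psi*(mu/rho) (approached as mu R -> 0) and the
    opaque limit 2 Psi / (rho pi R) (approached as mu R -> inf).
    """
    if min(energy_fluence_J_per_m2, mu_over_rho_cm2_per_g, density_g_per_cm3, radius_mm) <= 0:
        raise ValueError("all dose parameters must be positive")
    R = radius_mm * 1e-3  # m
    rho = density_g_per_cm3 * 1e3  # kg/m^3
    mu = mu_over_rho_cm2_per_g * density_g_per_cm3 * 1e2  # 1/m

    integral, err = integrate.quad(
        lambda x: 1.0 - np.exp(-mu * 2.0 * np.sqrt(max(R * R - x * x, 0.0))), -R, R,
        epsabs=1e-14, epsrel=1e-12, limit=200,
    )
    if err > max(1e-10, 1e-6 * abs(integral)):
        raise RuntimeError(f"chord integral did not converge (err={err:g})")
    return float(energy_fluence_J_per_m2 * integral / (rho * np.pi * R * R))


# ---------------------------------------------------------------------------
# Scan scheduling
# ---------------------------------------------------------------------------


def build_scan_schedule(
    protocol: ProtocolSpec, include_end_of_relaxation: bool = False
) -> np.ndarray:
    """Tomographic scan trigger times (s) for a protocol.

    CL: ``n_scans`` equidistant triggers at ``i*T/n`` for ``i = 1..n``
    over the ramp duration T.  StR: one trigger per scan offset after
    each compression peak (offset 0 is the peak itself); the optional
    flag adds a trigger at the end of each hold.  The nominal StR plan
    (2 steps x 7 offsets) gives 14 triggers, 16 with the flag.
    """
    if protocol.kind == "CL":
        T = protocol.duration_s
        n = protocol.n_scans
        triggers = np.array([i * T / n for i in range(1, n + 1)])
    else:
        rate = protocol.strain_rate_pct_per_s
        triggers_list: list[float] = []
        t0, prev = 0.0, 0.0
        for target, relax in zip(protocol.target_strains_pct, protocol.relaxation_s):
            t_peak = t0 + (target - prev) / rate
            for off in protocol.scan_offsets_s:
                triggers_list.append(t_peak + off)
            if include_end_of_relaxation:
                triggers_list.append(t_peak + relax)
            t0 = t_peak + relax
            prev = target
        # coinciding triggers (e.g. a 600 s offset meeting the end of a
        # 600 s hold) are kept as distinct scheduled scans
        triggers = np.asarray(sorted(triggers_list))
    if np.any(triggers > protocol.duration_s + 1e-9):
        raise ValueError("scan trigger beyond protocol duration")
    return triggers
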