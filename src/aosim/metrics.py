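"""Quantitative image analysis: bead FWHM, pseudo-widefield, frequency-space
resolution, and SIM modulation-contrast quality control.

Resolution is estimated two ways, mirroring standard SIM characterisation
practice: (1) Gaussian fits to sub-resolution bead images, reported as FWHM
= 2 sqrt(2 ln 2) sigma laterally and axially; (2) the support of the OTF,
found as the spatial frequency at which the normalised logarithmic power
spectrum falls to 0.01, converted to the spatial domain as 1/frequency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max

from .scope import RawSIMStack

__all__ = [
    "FWHMReport",
    "SpectralReport",
    "pseudo_widefield",
    "detect_beads",
    "bead_fwhm",
    "spectral_resolution",
    "modulation_contrast",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


def pseudo_widefield(stack: RawSIMStack) -> np.ndarray:
    """Average the raw SI frames over phases and angles per (z, channel).

    Because the five pattern phases sum to uniform illumination, this equals
    the widefield image of the same scene (up to noise).  Returns an array
    (z, channel, y, x).
    """
    data = stack.data
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))[:, :4]
        raise ValueError(
            f"missing/invalid frames at (phase, angle, z, channel) indices "
            f"{[tuple(int(v) for v in b) for b in bad[:5]]}")
    return data.mean(axis=(0, 1))


def detect_beads(volume: np.ndarray,
                 min_separation_vox: int = 5,
                 intensity_floor: float = 0.2) -> np.ndarray:
    """Local-maximum bead detection with sub-voxel centroid refinement.

    ``intensity_floor`` is relative to the volume maximum.  Accepts 2D or 3D
    input; returns an (n, ndim) array of sub-voxel coordinates (may be
    empty).
    """
    vol = np.asarray(volume, dtype=float)
    if vol.max() <= 0:
        return np.empty((0, vol.ndim))
    thr = intensity_floor * vol.max()
    peaks = peak_local_max(vol, min_distance=min_separation_vox,
                           threshold_abs=thr, exclude_border=False)
    out = []
    for p in peaks:
        sl = tuple(slice(max(c - 1, 0), min(c + 2, s))
                   for c, s in zip(p, vol.shape))
        w = vol[sl]
        grids = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl],
                            indexing="ij")
        wsum = w.sum()
        out.append([float((g * w).sum() / wsum) for g in grids])
    return np.asarray(out) if out else np.empty((0, vol.ndim))


def _gauss1d(x, amp, mu, sigma, offset):
    return offset + amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_profile(profile: np.ndarray, step_nm: float,
                 center: float) -> Tuple[float, float]:
    """Gaussian-plus-offset fit along one axis; returns (FWHM nm, R^2)."""
    x = np.arange(len(profile), dtype=float)
    p0 = [max(profile.max() - profile.min(), 1e-12), center,
          max(len(profile) / 8.0, 1.0), float(profile.min())]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(_gauss1d, x, profile, p0=p0,
                            bounds=([0, 0, 0.2, -np.inf],
                                    [np.inf, len(profile), len(profile),
                                     np.inf]),
                            maxfev=5000)
    resid = profile - _gauss1d(x, *popt)
    ss_tot = float(((profile - profile.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    return FWHM_PER_SIGMA * popt[2] * step_nm, r2


@dataclass
class FWHMReport:
    """Per-bead lateral and axial FWHM with sample statistics."""

    lateral_fwhm_nm: List[float]
    axial_fwhm_nm: List[float]
    diagnostics: List[dict]
    rejected: List[dict]
    lateral_mean_nm: float = 0.0
    lateral_sd_nm: float = 0.0
    axial_mean_nm: float = 0.0
    axial_sd_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.lateral_fwhm_nm:
            self.lateral_mean_nm = float(np.mean(self.lateral_fwhm_nm))
            self.lateral_sd_nm = float(np.std(self.lateral_fwhm_nm))
        if self.axial_fwhm_nm:
            self.axial_mean_nm = float(np.mean(self.axial_fwhm_nm))
            self.axial_sd_nm = float(np.std(self.axial_fwhm_nm))


def bead_fwhm(volume: np.ndarray,
              locations: Sequence[Sequence[float]],
              voxel_xy_nm: float,
              voxel_z_nm: float = 125.0,
              fit_halfwidth_vox: int = 8,
              r2_min: float = 0.95,
              diffraction_fwhm_nm: Optional[float] = None,
              neighbor_factor: float = 10.0) -> FWHMReport:
    """Per-bead 1D Gaussian fits along x, y (averaged to the lateral value)
    and z; rejection rules: fit R^2 below ``r2_min``, FWHM above 3x the
    diffraction estimate (when given), or a neighbour closer than
    ``neighbor_factor`` x FWHM."""
    vol = np.asarray(volume, dtype=float)
    is3d = vol.ndim == 3 and vol.shape[0] > 1
    locs = np.asarray(locations, dtype=float)
    if locs.size == 0:
        raise ValueError("no bead locations supplied")
    lat, ax, diags, rejected = [], [], [], []
    for bead_i, loc in enumerate(locs):
        if vol.ndim == 3:
            cz, cy, cx = loc
        else:
            cy, cx = loc
            cz = 0.0
        iy, ix = int(round(cy)), int(round(cx))
        iz = int(round(cz))
        h = fit_halfwidth_vox
        reasons = []
        try:
            if vol.ndim == 3:
                row = vol[iz, iy, max(ix - h, 0):ix + h + 1]
                col = vol[iz, max(iy - h, 0):iy + h + 1, ix]
            else:
                row = vol[iy, max(ix - h, 0):ix + h + 1]
                col = vol[max(iy - h, 0):iy + h + 1, ix]
            fx, r2x = _fit_profile(row, voxel_xy_nm, cx - max(ix - h, 0))
            fy, r2y = _fit_profile(col, voxel_xy_nm, cy - max(iy - h, 0))
            lateral = 0.5 * (fx + fy)
            r2_lat = min(r2x, r2y)
            if is3d:
                prof_z = vol[:, iy, ix]
                fz, r2z = _fit_profile(prof_z, voxel_z_nm, cz)
            else:
                fz, r2z = float("nan"), 1.0
        except RuntimeError:
            rejected.append({"bead": bead_i, "reason": "fit failed"})
            continue
        if min(r2_lat, r2z) < r2_min:
            reasons.append(f"fit R^2 {min(r2_lat, r2z):.3f} < {r2_min}")
        if diffraction_fwhm_nm is not None and lateral > 3 * diffraction_fwhm_nm:
            reasons.append("FWHM > 3x diffraction estimate")
        if len(locs) > 1:
            others = np.delete(locs, bead_i, axis=0)
            d = np.min(np.linalg.norm(
                (others - loc) * np.array([voxel_z_nm, voxel_xy_nm,
                                           voxel_xy_nm][:vol.ndim]),
                axis=1))
            if d < neighbor_factor * lateral:
                reasons.append(f"neighbour within {neighbor_factor}x FWHM")
        if reasons:
            rejected.append({"bead": bead_i, "reason": "; ".join(reasons)})
            continue
        lat.append(lateral)
        ax.append(fz)
        diags.append({"bead": bead_i, "fwhm_x_nm": fx, "fwhm_y_nm": fy,
                      "fwhm_z_nm": fz, "r2_lateral": r2_lat, "r2_axial": r2z})
    if not lat:
        raise RuntimeError(f"all {len(locs)} beads rejected: {rejected}")
    axial = [a for a in ax if not math.isnan(a)]
    return FWHMReport(lat, axial, diags, rejected)


@dataclass
class SpectralReport:
    """OTF-support resolution estimate from the normalised log power."""

    lateral_freq_um: np.ndarray
    lateral_profile: np.ndarray  # normalised log power, max 1
    axial_freq_um: np.ndarray
    axial_profile: np.ndarray
    threshold: float
    lateral_cutoff_um: Optional[float]   # 1/um
    axial_cutoff_um: Optional[float]
    lateral_resolution_nm: Optional[float]
    axial_resolution_nm: Optional[float]
    grid_limited_lateral: bool = False
    grid_limited_axial: bool = False


def _normalize_log_profile(profile_power: np.ndarray,
                           floor_fraction: float = 0.05,
                           dynamic_range_decades: float = 8.0) -> np.ndarray:
    """Log10 power scaled to [0, 1] between its noise floor and maximum.

    The noise floor is the mean log power over the highest-frequency
    ``floor_fraction`` of bins, but never more than
    ``dynamic_range_decades`` below the maximum: noiseless synthetic data
    would otherwise push the floor down to numerical leakage, tens of
    decades below anything a camera can record.  Values below the floor are
    clipped to it (the pre-display noise threshold).
    """
    logp = np.log10(np.clip(profile_power, 1e-300, None))
    n_floor = max(int(len(logp) * floor_fraction), 1)
    top = float(logp.max())
    floor = max(float(logp[-n_floor:].mean()), top - dynamic_range_decades)
    if top <= floor:
        return np.zeros_like(logp)
    norm = (np.clip(logp, floor, None) - floor) / (top - floor)
    return norm


def _first_crossing(freq: np.ndarray, profile: np.ndarray,
                    threshold: float) -> Tuple[Optional[float], bool]:
    """First crossing below threshold beyond the profile maximum, linearly
    interpolated between bins; (None, True) when it never crosses."""
    start = int(np.argmax(profile))
    below = profile[start:] < threshold
    if not below.any():
        return None, True
    idx = start + int(np.argmax(below))
    if idx == 0:
        return float(freq[0]), False
    f0, f1 = freq[idx - 1], freq[idx]
    p0, p1 = profile[idx - 1], profile[idx]
    if p0 == p1:
        return float(f1), False
    return float(f0 + (p0 - threshold) / (p0 - p1) * (f1 - f0)), False


def spectral_resolution(volume: np.ndarray,
                        voxel_xy_nm: float,
                        voxel_z_nm: float,
                        threshold: float = 0.01,
                        window: bool = True) -> SpectralReport:
    """OTF-support resolution from the 3D power spectrum.

    The lateral profile is the radial average of the central kxy plane; the
    axial profile folds the two 0 -> +/-kz directions of the central kxz
    plane and then averages along kx.  Both log-power profiles are
    normalised to [0, 1] between noise floor and maximum, and the first
    crossing below ``threshold`` (linearly interpolated between bins)
    defines the cutoff; resolution is its reciprocal.  If a profile never
    crosses, the grid-limited resolution is reported and flagged.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 2:
        vol = vol[None]
    nz, ny, nx = vol.shape
    if min(ny, nx) < 32:
        raise ValueError("volume must be at least 32 voxels laterally")
    vol = vol - vol.mean()  # DC offset carries no resolution information
    if window:
        wz = np.hanning(nz) if nz > 1 else np.ones(1)
        w = (wz[:, None, None] * np.hanning(ny)[None, :, None]
             * np.hanning(nx)[None, None, :])
        vol = vol * w
    spec = np.fft.fftshift(np.fft.fftn(vol))
    power = np.abs(spec) ** 2
    cz, cy, cx = nz // 2, ny // 2, nx // 2
    # lateral: radial average over the central kxy plane
    kxy = power[cz]
    fy = np.fft.fftshift(np.fft.fftfreq(ny, voxel_xy_nm))
    fx = np.fft.fftshift(np.fft.fftfreq(nx, voxel_xy_nm))
    f_r = np.hypot(fy[:, None], fx[None, :])
    df = 1.0 / (max(ny, nx) * voxel_xy_nm)
    n_bins = int(f_r.max() / df) + 1
    bins = (f_r / df).astype(int)
    radial = np.bincount(bins.ravel(), weights=kxy.ravel(),
                         minlength=n_bins + 1)
    counts = np.bincount(bins.ravel(), minlength=n_bins + 1)
    valid = counts > 0
    lat_freq = (np.arange(len(radial))[valid] * df)
    lat_power = radial[valid] / counts[valid]
    keep = lat_freq <= min(fy.max(), fx.max())
    lat_freq, lat_power = lat_freq[keep], lat_power[keep]
    lat_profile = _normalize_log_profile(lat_power)
    lat_cut, lat_limited = _first_crossing(lat_freq, lat_profile, threshold)
    # axial: central kxz plane, fold +/-kz, average along kx
    if nz > 1:
        kxz = power[:, cy, :]  # (kz, kx)
        fz = np.fft.fftshift(np.fft.fftfreq(nz, voxel_z_nm))
        pos = fz >= 0
        folded = np.empty((pos.sum(), nx))
        for i, izp in enumerate(np.where(pos)[0]):
            dz = fz[izp]
            izn = np.argmin(np.abs(fz + dz))
            folded[i] = 0.5 * (kxz[izp] + kxz[izn])
        ax_power = folded.mean(axis=1)
        ax_freq = fz[pos]
        order = np.argsort(ax_freq)
        ax_freq, ax_power = ax_freq[order], ax_power[order]
        ax_profile = _normalize_log_profile(ax_power)
        ax_cut, ax_limited = _first_crossing(ax_freq, ax_profile, threshold)
    else:
        ax_freq = np.zeros(1)
        ax_profile = np.ones(1)
        ax_cut, ax_limited = None, True
    to_um = 1e3  # 1/nm -> 1/um

    def _res(cut):
        return None if cut in (None, 0.0) else 1.0 / cut  # nm

    if lat_limited:
        lat_cut = float(lat_freq[-1])
    if nz > 1 and ax_limited:
        ax_cut = float(ax_freq[-1]) if ax_freq[-1] > 0 else None
    return SpectralReport(
        lateral_freq_um=lat_freq * to_um,
        lateral_profile=lat_profile,
        axial_freq_um=ax_freq * to_um,
        axial_profile=ax_profile if nz > 1 else np.ones(1),
        threshold=threshold,
        lateral_cutoff_um=None if lat_cut is None else lat_cut * to_um,
        axial_cutoff_um=None if ax_cut is None else ax_cut * to_um,
        lateral_resolution_nm=_res(lat_cut),
        axial_resolution_nm=_res(ax_cut),
        grid_limited_lateral=lat_limited,
        grid_limited_axial=ax_limited if nz > 1 else True,
    )


def modulation_contrast(stack: RawSIMStack) -> np.ndarray:
    """Per-(angle, z, channel) stripe contrast of the raw SI data.

    For each pixel the five-phase sequence is Fourier-analysed; the contrast
    is twice the single-cycle amplitude over the DC amplitude, aggregated as
    a ratio of pixel means (2 mean|X1| / mean X0).  A pure sinusoidal
    modulation of depth m scores exactly m.
    """
    data = stack.data  # (phase, angle, z, ch, y, x)
    n_phases = data.shape[0]
    k = np.exp(-2j * np.pi * np.arange(n_phases) / n_phases)
    x1 = np.tensordot(k, data, axes=(0, 0))  # (angle, z, ch, y, x)
    x0 = data.sum(axis=0)
    num = 2.0 * np.abs(x1).mean(axis=(-2, -1))
    den = x0.mean(axis=(-2, -1))
    with np.errstate(divide="ignore", invalid="ignore"):
        contrast = np.where(den > 0, num / den, 0.0)
    return contrast
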