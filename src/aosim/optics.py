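"""Scalar Fourier-optics engine: pupils, PSFs, OTFs, Strehl ratio.

Conventions (fixed here, used everywhere):

* Arrays are ordered ``(z, y, x)``.
* The pupil is sampled on the lateral spatial-frequency grid of the target
  image, ``f = fftfreq(N, voxel_xy)`` in 1/nm, so PSFs land directly on the
  declared voxel grid.  The pupil (emission) cutoff is ``NA / lambda_em``;
  with Nyquist-sampled voxels this leaves >= 2x zero-padding around the
  aperture.
* Real-space and frequency-space volumes are returned with the origin (PSF
  peak / OTF DC) at the central index ``N // 2`` of each axis.
* Axial defocus uses the exact high-NA phase
  ``k * n * z * sqrt(1 - (lambda * f / n)**2)``; a paraxial (parabolic)
  approximation is available behind a flag.
* Frequency steps are reported in 1/um to match the usual power-spectrum
  scale bars (1 nm^-1 == 1000 um^-1).

The model is scalar: adequate for exercising correction logic and resolution
bookkeeping, not for quantitative vectorial high-NA PSF shapes (see the
methods note for the accuracy caveat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .zernike import ZernikeVector, zernike_eval

__all__ = [
    "OpticalConfig",
    "PupilFunction",
    "PSFVolume",
    "OTFVolume",
    "build_pupil",
    "pupil_to_psf",
    "psf_to_otf",
    "strehl",
]


@dataclass
class OpticalConfig:
    """Physical parameters of the (virtual) microscope.

    Defaults describe a 60x/1.1 NA water-immersion system imaging a green
    fluorophore (488 nm excitation / 525 nm emission).
    """

    na: float = 1.1
    lambda_ex_nm: float = 488.0
    lambda_em_nm: float = 525.0
    n_immersion: float = 1.33
    n_sample: float = 1.33
    voxel_xy_nm: float = 100.0
    voxel_z_nm: float = 125.0
    pupil_grid_size: int = 256

    def __post_init__(self) -> None:
        if not 0 < self.na < self.n_immersion:
            raise ValueError(
                f"require 0 < NA < n_immersion, got NA={self.na}, "
                f"n_immersion={self.n_immersion}"
            )
        for name in ("lambda_ex_nm", "lambda_em_nm", "voxel_xy_nm",
                     "voxel_z_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.pupil_grid_size < 16:
            raise ValueError("pupil_grid_size must be >= 16")
        if self.voxel_xy_nm > self.lambda_em_nm / (4.0 * self.na) + 1e-9:
            warnings.warn(
                "voxel_xy does not Nyquist-sample the emission cutoff "
                f"(need <= {self.lambda_em_nm / (4 * self.na):.1f} nm, got "
                f"{self.voxel_xy_nm} nm); SIM-resolution renders will alias",
                stacklevel=2,
            )

    # --- derived cutoffs (1/nm) --------------------------------------------
    @property
    def emission_cutoff(self) -> float:
        """Incoherent (widefield) lateral OTF cutoff, 2*NA/lambda_em [1/nm]."""
        return 2.0 * self.na / self.lambda_em_nm

    @property
    def excitation_coherent_cutoff(self) -> float:
        """Highest lateral frequency a +/-1-order interference pattern can
        carry, NA/lambda_ex [1/nm]."""
        return self.na / self.lambda_ex_nm

    @property
    def pupil_radius(self) -> float:
        """Pupil (coherent emission) cutoff NA/lambda_em [1/nm]."""
        return self.na / self.lambda_em_nm


@dataclass
class PupilFunction:
    """Complex pupil field sampled on the image frequency grid.

    ``field`` has DC at index [0, 0] (numpy fft layout); ``rho``/``theta``
    are the normalized pupil coordinates and ``mask`` the binary aperture.
    """

    field: np.ndarray
    mask: np.ndarray
    rho: np.ndarray
    theta: np.ndarray
    config: OpticalConfig
    wavelength_nm: float

    @property
    def grid_size(self) -> int:
        return self.field.shape[0]

    def power(self) -> float:
        return float(np.sum(np.abs(self.field) ** 2))

    def phase_rms(self) -> float:
        """RMS of the pupil phase over the aperture, radians."""
        ph = np.angle(self.field[self.mask])
        return float(np.sqrt(np.mean((ph - ph.mean()) ** 2)))


@dataclass
class PSFVolume:
    """3D intensity PSF on a declared voxel grid; origin at ``center``."""

    intensity: np.ndarray  # (z, y, x), >= 0
    voxel_xy_nm: float
    voxel_z_nm: float
    center: Tuple[int, int, int]
    normalization: str = "sum"  # "sum" | "peak" | "none"
    z_planes_nm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if np.any(self.intensity < -1e-12):
            raise ValueError("PSF intensity must be non-negative")
        if self.normalization == "sum":
            s = self.intensity.sum()
            if not np.isclose(s, 1.0, atol=1e-9):
                raise ValueError(f"sum-normalized PSF sums to {s}, not 1")
        elif self.normalization == "peak":
            if not np.isclose(self.intensity.max(), 1.0, atol=1e-9):
                raise ValueError("peak-normalized PSF max is not 1")

    @property
    def peak(self) -> float:
        return float(self.intensity.max())

    def renormalized(self, normalization: str) -> "PSFVolume":
        if normalization == "sum":
            data = self.intensity / self.intensity.sum()
        elif normalization == "peak":
            data = self.intensity / self.intensity.max()
        else:
            raise ValueError(normalization)
        return PSFVolume(data, self.voxel_xy_nm, self.voxel_z_nm,
                         self.center, normalization, self.z_planes_nm)


@dataclass
class OTFVolume:
    """Complex OTF with DC at the central index of each axis."""

    data: np.ndarray  # (z, y, x) complex
    freq_step_um: Tuple[float, float, float]  # per axis (z, y, x), 1/um
    center: Tuple[int, int, int] = field(default=None)  # type: ignore

    def __post_init__(self) -> None:
        if self.center is None:
            self.center = tuple(s // 2 for s in self.data.shape)

    @property
    def dc_value(self) -> complex:
        return complex(self.data[self.center])


def _frequency_grid(n: int, voxel_nm: float) -> Tuple[np.ndarray, np.ndarray]:
    f = np.fft.fftfreq(n, d=voxel_nm)  # 1/nm, DC first
    fx, fy = np.meshgrid(f, f, indexing="xy")
    return fy, fx


def build_pupil(config: OpticalConfig,
                aberration: Optional[ZernikeVector] = None,
                grid_size: Optional[int] = None,
                wavelength_nm: Optional[float] = None) -> PupilFunction:
    """Uniform-amplitude circular pupil with a Zernike phase.

    The phase inside the aperture is ``sum_j a_j Z_j(rho, theta)`` with the
    RMS-normalized polynomials, so the pupil phase RMS equals the coefficient
    quadrature sum.
    """
    n = int(grid_size or config.pupil_grid_size)
    lam = float(wavelength_nm or config.lambda_em_nm)
    fy, fx = _frequency_grid(n, config.voxel_xy_nm)
    f_r = np.hypot(fx, fy)
    f_max = config.na / lam
    nyquist = 0.5 / config.voxel_xy_nm
    if f_max >= nyquist:
        raise ValueError(
            f"pupil support ({f_max:.4g}/nm) exceeds the grid Nyquist "
            f"frequency ({nyquist:.4g}/nm); decrease voxel_xy or NA"
        )
    rho = f_r / f_max
    theta = np.arctan2(fy, fx)
    mask = rho <= 1.0
    phase = np.zeros((n, n))
    if aberration is not None:
        for j in aberration:
            phase[mask] += aberration[j] * zernike_eval(j, rho[mask],
                                                        theta[mask])
    fld = np.where(mask, np.exp(1j * phase), 0.0)
    return PupilFunction(fld, mask, rho, theta, config, lam)


def _axial_phase(pupil: PupilFunction, z_nm: float,
                 paraxial: bool = False) -> np.ndarray:
    cfg = pupil.config
    lam = pupil.wavelength_nm
    n_imm = cfg.n_immersion
    k = 2.0 * np.pi * n_imm / lam
    sin2 = np.clip((cfg.na * pupil.rho / n_imm) ** 2, 0.0, 1.0)
    if paraxial:
        return k * z_nm * (1.0 - 0.5 * sin2)
    return k * z_nm * np.sqrt(1.0 - sin2)


def pupil_to_psf(pupil: PupilFunction,
                 z_planes_nm: Sequence[float],
                 normalization: str = "sum",
                 paraxial: bool = False) -> PSFVolume:
    """Scalar-diffraction intensity PSF, one lateral FFT per z plane.

    ``z_planes_nm`` is typically symmetric about 0; the returned volume is
    fftshifted so the in-focus peak of an unaberrated pupil sits at the
    central pixel, and ``center`` points at (z==0 plane, N//2, N//2).
    """
    z_planes = np.asarray(z_planes_nm, dtype=float)
    n = pupil.grid_size
    vol = np.empty((len(z_planes), n, n))
    for i, z in enumerate(z_planes):
        fld = pupil.field * np.exp(1j * _axial_phase(pupil, z, paraxial))
        amp = np.fft.ifft2(fld)
        vol[i] = np.fft.fftshift(np.abs(amp) ** 2)
    iz0 = int(np.argmin(np.abs(z_planes)))
    if normalization == "sum":
        vol /= vol.sum()
    elif normalization == "peak":
        vol /= vol.max()
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return PSFVolume(vol, pupil.config.voxel_xy_nm,
                     pupil.config.voxel_z_nm
                     if len(z_planes) < 2
                     else float(np.diff(np.sort(z_planes)).mean()),
                     (iz0, n // 2, n // 2), normalization, z_planes)


def psf_to_otf(psf: PSFVolume) -> OTFVolume:
    """3D DFT of the PSF with DC shifted to the central index.

    Frequency steps are ``1 / (N * voxel)`` per axis, reported in 1/um.
    """
    if not np.all(np.isfinite(psf.intensity)):
        raise ValueError("PSF contains non-finite values")
    data = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(psf.intensity)))
    nz, ny, nx = psf.intensity.shape
    step = (1e3 / (nz * psf.voxel_z_nm),
            1e3 / (ny * psf.voxel_xy_nm),
            1e3 / (nx * psf.voxel_xy_nm))
    return OTFVolume(data, step)


def strehl(psf: PSFVolume, psf_ideal: PSFVolume) -> float:
    """Peak-intensity ratio of an aberrated PSF to the diffraction-limited
    one, both normalized to equal total energy on the same grid."""
    if psf.intensity.shape != psf_ideal.intensity.shape:
        raise ValueError(
            f"grid mismatch: {psf.intensity.shape} vs "
            f"{psf_ideal.intensity.shape}"
        )
    if not (np.isclose(psf.voxel_xy_nm, psf_ideal.voxel_xy_nm)
            and np.isclose(psf.voxel_z_nm, psf_ideal.voxel_z_nm)):
        raise ValueError("voxel-size mismatch between PSFs")
    a = psf.intensity / psf.intensity.sum()
    b = psf_ideal.intensity / psf_ideal.intensity.sum()
    return float(a.max() / b.max())
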