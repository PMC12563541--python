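"""The virtual specimen + microscope test bench.

Everything the correction, refocusing and QC modules need from hardware is
emulated here: seeded phantoms (bead fields, filaments, epithelial mosaics),
a depth-proportional aberration model, a deformable-mirror (DM) model with
fidelity/clip/creep imperfections, three-beam structured-illumination
patterns, and noisy widefield / raw-SIM image formation.

Image formation is locally shift-invariant: each focal plane is rendered by
2D convolution of every object plane with the corresponding slice of the 3D
PSF computed for the aberration at that depth.  Photon conversion is
calibrated so that a unit-amplitude in-focus point emitter in an unaberrated
system yields ``photon_budget`` expected peak photons; aberrations then
reduce the signal by the Strehl factor, as on a real instrument.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .optics import OpticalConfig, PSFVolume, build_pupil, pupil_to_psf
from .zernike import ZernikeVector

__all__ = [
    "Phantom",
    "DepthAberrationModel",
    "DMModel",
    "SIMPattern",
    "NoiseModel",
    "RawSIMStack",
    "VirtualScope",
    "make_bead_phantom",
    "make_filament_phantom",
    "make_mosaic_phantom",
    "aberration_at_depth",
    "dm_apply",
    "sim_pattern",
    "render_widefield",
    "render_sim_stack",
]

N_PHASES = 5
N_ANGLES = 3


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    """A synthetic specimen: a non-negative intensity volume plus the
    parameters and seed that regenerate it bit-identically."""

    kind: str
    volume: np.ndarray  # (z, y, x)
    voxel_xy_nm: float
    voxel_z_nm: float
    params: dict = field(default_factory=dict)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if np.any(self.volume < 0):
            raise ValueError("phantom intensities must be non-negative")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.volume.shape  # type: ignore[return-value]


def _splat_sphere(volume: np.ndarray, center_vox: Sequence[float],
                  radius_nm: float, voxel_xy: float, voxel_z: float,
                  oversample: int = 3) -> None:
    """Add a solid sphere (projected to a disk column for single-plane
    volumes) with sub-voxel anti-aliasing by supersampling."""
    nz, ny, nx = volume.shape
    cz, cy, cx = center_vox
    rz = max(radius_nm / voxel_z, 1e-6)
    rxy = max(radius_nm / voxel_xy, 1e-6)
    z0, z1 = int(math.floor(cz - rz - 1)), int(math.ceil(cz + rz + 1))
    y0, y1 = int(math.floor(cy - rxy - 1)), int(math.ceil(cy + rxy + 1))
    x0, x1 = int(math.floor(cx - rxy - 1)), int(math.ceil(cx + rxy + 1))
    z0, y0, x0 = max(z0, 0), max(y0, 0), max(x0, 0)
    z1, y1, x1 = min(z1, nz - 1), min(y1, ny - 1), min(x1, nx - 1)
    if z1 < z0 or y1 < y0 or x1 < x0:
        return
    sub = (np.arange(oversample) + 0.5) / oversample - 0.5
    if nz == 1:
        # thin scene: use the column integral of the sphere (a projected disk)
        yy = np.arange(y0, y1 + 1)
        xx = np.arange(x0, x1 + 1)
        acc = np.zeros((len(yy), len(xx)))
        for dy in sub:
            for dx in sub:
                d2 = (((yy[:, None] + dy - cy) * voxel_xy) ** 2
                      + ((xx[None, :] + dx - cx) * voxel_xy) ** 2)
                col = np.sqrt(np.clip(radius_nm ** 2 - d2, 0.0, None))
                acc += 2.0 * col / radius_nm  # peak 2R normalized to 2
        volume[0, y0:y1 + 1, x0:x1 + 1] += acc / oversample ** 2
        return
    zz = np.arange(z0, z1 + 1)
    yy = np.arange(y0, y1 + 1)
    xx = np.arange(x0, x1 + 1)
    acc = np.zeros((len(zz), len(yy), len(xx)))
    for dz in sub:
        for dy in sub:
            for dx in sub:
                d2 = (((zz[:, None, None] + dz - cz) * voxel_z) ** 2
                      + ((yy[None, :, None] + dy - cy) * voxel_xy) ** 2
                      + ((xx[None, None, :] + dx - cx) * voxel_xy) ** 2)
                acc += (d2 <= radius_nm ** 2)
    volume[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1] += acc / oversample ** 3


def make_bead_phantom(n_beads: int,
                      diameter_nm: float = 100.0,
                      fov: Tuple[int, int, int] = (1, 128, 128),
                      min_separation_nm: float = 1000.0,
                      seed: int = 0,
                      config: Optional[OpticalConfig] = None,
                      margin_nm: float = 500.0,
                      bead_z_vox: Optional[float] = None) -> Phantom:
    """Seeded field of sub-resolution fluorescent beads.

    Beads are placed uniformly at random (rejecting placements closer than
    ``min_separation_nm``) and rendered as diameter-matched spheres with
    sub-voxel anti-aliasing.  ``fov`` is (nz, ny, nx) voxels; a single-plane
    FOV renders projected disks.  Raises if the packing is infeasible after
    bounded retries.
    """
    cfg = config or OpticalConfig()
    nz, ny, nx = fov
    rng = np.random.default_rng(seed)
    vol = np.zeros(fov, dtype=float)
    margin_xy = margin_nm / cfg.voxel_xy_nm
    if ny - 2 * margin_xy <= 0 or nx - 2 * margin_xy <= 0:
        raise ValueError("FOV too small for the requested margin")
    centers: List[Tuple[float, float, float]] = []
    if n_beads == 1:
        cz = (nz - 1) / 2 if bead_z_vox is None else bead_z_vox
        centers.append((cz, (ny - 1) / 2.0, (nx - 1) / 2.0))
    else:
        max_tries = 200 * n_beads
        tries = 0
        while len(centers) < n_beads:
            if tries > max_tries:
                raise RuntimeError(
                    f"could not place {n_beads} beads with "
                    f"{min_separation_nm} nm separation in FOV {fov}"
                )
            tries += 1
            cz = ((nz - 1) / 2 if bead_z_vox is not None or nz == 1
                  else rng.uniform(0, nz - 1))
            if bead_z_vox is not None:
                cz = bead_z_vox
            cy = rng.uniform(margin_xy, ny - 1 - margin_xy)
            cx = rng.uniform(margin_xy, nx - 1 - margin_xy)
            ok = True
            for oz, oy, ox in centers:
                d = math.hypot((cy - oy) * cfg.voxel_xy_nm,
                               (cx - ox) * cfg.voxel_xy_nm)
                if d < min_separation_nm:
                    ok = False
                    break
            if ok:
                centers.append((cz, cy, cx))
    for c in centers:
        _splat_sphere(vol, c, diameter_nm / 2.0, cfg.voxel_xy_nm,
                      cfg.voxel_z_nm)
    return Phantom("bead_field", vol, cfg.voxel_xy_nm, cfg.voxel_z_nm,
                   params={"n_beads": n_beads, "diameter_nm": diameter_nm,
                           "min_separation_nm": min_separation_nm,
                           "centers_vox": centers},
                   seed=seed)


def make_filament_phantom(n_filaments: int = 5,
                          width_nm: float = 100.0,
                          curvature_scale: float = 0.2,
                          fov: Tuple[int, int, int] = (1, 128, 128),
                          seed: int = 0,
                          config: Optional[OpticalConfig] = None) -> Phantom:
    """Curvilinear sub-resolution tubules (microtubule / ER-like scene).

    Each filament is a smooth random walk: the heading angle diffuses with
    standard deviation ``curvature_scale`` radians per step (0 gives straight
    lines).  Tubes are rendered with a Gaussian cross-section whose FWHM is
    ``width_nm``.
    """
    cfg = config or OpticalConfig()
    nz, ny, nx = fov
    rng = np.random.default_rng(seed)
    vol = np.zeros(fov, dtype=float)
    sigma_vox = width_nm / 2.354820045 / cfg.voxel_xy_nm
    step_vox = max(sigma_vox / 2.0, 0.3)
    yy, xx = np.mgrid[0:ny, 0:nx]
    plane = np.zeros((ny, nx))
    for _ in range(n_filaments):
        y = rng.uniform(0.1 * ny, 0.9 * ny)
        x = rng.uniform(0.1 * nx, 0.9 * nx)
        ang = rng.uniform(0, 2 * np.pi)
        n_steps = int(1.5 * max(ny, nx) / step_vox)
        for _ in range(n_steps):
            ang += rng.normal(0.0, curvature_scale) * math.sqrt(step_vox)
            y += step_vox * math.sin(ang)
            x += step_vox * math.cos(ang)
            if not (0 <= y < ny and 0 <= x < nx):
                break
            y0, y1 = max(int(y - 4 * sigma_vox), 0), min(int(y + 4 * sigma_vox) + 1, ny)
            x0, x1 = max(int(x - 4 * sigma_vox), 0), min(int(x + 4 * sigma_vox) + 1, nx)
            d2 = ((yy[y0:y1, x0:x1] - y) ** 2 + (xx[y0:y1, x0:x1] - x) ** 2)
            plane[y0:y1, x0:x1] += np.exp(-d2 / (2 * sigma_vox ** 2))
    vol[nz // 2] = plane
    return Phantom("filaments", vol, cfg.voxel_xy_nm, cfg.voxel_z_nm,
                   params={"n_filaments": n_filaments, "width_nm": width_nm,
                           "curvature_scale": curvature_scale},
                   seed=seed)


def make_mosaic_phantom(n_cells: int = 30,
                        membrane_width_nm: float = 150.0,
                        fov: Tuple[int, int, int] = (1, 128, 128),
                        seed: int = 0,
                        config: Optional[OpticalConfig] = None) -> Phantom:
    """Epithelial-mosaic scene: labelled cell outlines of a packed cell
    layer, modelled as the boundaries of a nearest-seed (Voronoi) tiling."""
    cfg = config or OpticalConfig()
    nz, ny, nx = fov
    rng = np.random.default_rng(seed)
    pts = np.column_stack([rng.uniform(0, ny, n_cells),
                           rng.uniform(0, nx, n_cells)])
    yy, xx = np.mgrid[0:ny, 0:nx]
    d2 = ((yy[..., None] - pts[:, 0]) ** 2 + (xx[..., None] - pts[:, 1]) ** 2)
    labels = np.argmin(d2, axis=-1)
    edge = np.zeros((ny, nx), dtype=bool)
    edge[:-1] |= labels[:-1] != labels[1:]
    edge[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    from scipy.ndimage import gaussian_filter
    sigma_vox = membrane_width_nm / 2.354820045 / cfg.voxel_xy_nm
    plane = gaussian_filter(edge.astype(float), sigma_vox)
    if plane.max() > 0:
        plane /= plane.max()
    vol = np.zeros(fov)
    vol[nz // 2] = plane
    return Phantom("mosaic", vol, cfg.voxel_xy_nm, cfg.voxel_z_nm,
                   params={"n_cells": n_cells,
                           "membrane_width_nm": membrane_width_nm},
                   seed=seed)


# ---------------------------------------------------------------------------
# Depth aberrations and the deformable mirror
# ---------------------------------------------------------------------------

@dataclass
class DepthAberrationModel:
    """Sample-induced aberration as an affine function of imaging depth.

    Dominant aberrations such as spherical grow roughly in proportion to
    depth; ``slopes`` are rad/um per mode, ``offsets`` the depth-0 values.
    An optional seeded high-order perturbation adds per-mode random slopes
    (drawn once) to emulate specimen inhomogeneity.
    """

    slopes: Dict[int, float] = field(default_factory=dict)
    offsets: Dict[int, float] = field(default_factory=dict)
    perturb_modes: Tuple[int, ...] = ()
    perturb_sd: float = 0.0  # rad/um
    seed: Optional[int] = None
    reference_wavelength_nm: float = 525.0

    def __post_init__(self) -> None:
        self._perturb_slopes: Dict[int, float] = {}
        if self.perturb_modes and self.perturb_sd > 0:
            rng = np.random.default_rng(self.seed)
            for j in self.perturb_modes:
                self._perturb_slopes[int(j)] = float(
                    rng.normal(0.0, self.perturb_sd))

    def __call__(self, depth_um: float) -> ZernikeVector:
        return aberration_at_depth(self, depth_um)


def aberration_at_depth(model: DepthAberrationModel,
                        depth_um: float) -> ZernikeVector:
    """Evaluate the depth model; exact offsets at depth 0."""
    if depth_um < 0:
        raise ValueError("depth must be >= 0")
    coeffs: Dict[int, float] = {}
    for j, a in model.offsets.items():
        coeffs[int(j)] = coeffs.get(int(j), 0.0) + a
    for j, s in model.slopes.items():
        coeffs[int(j)] = coeffs.get(int(j), 0.0) + s * depth_um
    for j, s in model._perturb_slopes.items():
        coeffs[int(j)] = coeffs.get(int(j), 0.0) + s * depth_um
    coeffs = {j: a for j, a in coeffs.items() if a != 0.0}
    return ZernikeVector(coeffs, model.reference_wavelength_nm)


@dataclass
class DMModel:
    """Deformable-mirror response model.

    ``fidelity`` is the achievable fraction of a requested modal amplitude
    (scalar or per-mode); requests outside ``correctable_modes`` are not
    produced at all and are reported as uncorrectable residual.  ``clip_rad``
    bounds the per-mode amplitude.  The optional creep term drifts the
    achieved shape by ``creep_amplitude`` (fractional) with a single
    exponential time constant ``creep_tau_s`` after the shape is set.
    """

    correctable_modes: Tuple[int, ...] = tuple(range(2, 23))
    fidelity: Union[float, Dict[int, float]] = 1.0
    clip_rad: float = math.inf
    creep_amplitude: float = 0.0
    creep_tau_s: float = 30.0
    settle_time_ms: float = 1.0

    def mode_fidelity(self, j: int) -> float:
        if isinstance(self.fidelity, dict):
            return float(self.fidelity.get(int(j), 1.0))
        return float(self.fidelity)


def dm_apply(dm: DMModel, requested: ZernikeVector,
             t_s: float = 0.0) -> Tuple[ZernikeVector, dict]:
    """Mirror response to a requested modal shape.

    Returns the achieved shape and a report with the uncorrectable residual
    (modes outside the correctable set) and any clipping applied.
    """
    achieved: Dict[int, float] = {}
    residual: Dict[int, float] = {}
    clipped: List[int] = []
    correctable = set(int(j) for j in dm.correctable_modes)
    for j in requested:
        a = requested[j]
        if j not in correctable:
            residual[j] = a
            continue
        if abs(a) > dm.clip_rad:
            a = math.copysign(dm.clip_rad, a)
            clipped.append(j)
        a *= dm.mode_fidelity(j)
        if dm.creep_amplitude != 0.0:
            a *= 1.0 + dm.creep_amplitude * (1.0 - math.exp(-t_s / dm.creep_tau_s))
        achieved[j] = a
    report = {
        "uncorrectable": ZernikeVector(
            residual, requested.reference_wavelength_nm),
        "clipped_modes": clipped,
    }
    return (ZernikeVector(achieved, requested.reference_wavelength_nm),
            report)


# ---------------------------------------------------------------------------
# Structured illumination
# ---------------------------------------------------------------------------

@dataclass
class SIMPattern:
    """One structured-illumination state (angle x phase).

    The pattern is the interference of the 0 and +/-1 diffraction orders.
    ``k_frac`` is the lateral pattern frequency as a fraction of the
    excitation coherent cutoff NA/lambda_ex (the highest frequency the +/-1
    orders can carry); the default 0.8 reflects conservatively chosen line
    widths.  ``modulation_depth`` m in [0, 1] is the first-harmonic contrast
    at the focal plane; beam amplitudes are derived from it.
    """

    angle_index: int = 0
    phase_index: int = 0
    k_frac: float = 0.8
    axial: bool = True
    modulation_depth: float = 0.9
    azimuth_rad: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.angle_index < N_ANGLES:
            raise ValueError("angle_index must be 0..2")
        if not 0 <= self.phase_index < N_PHASES:
            raise ValueError("phase_index must be 0..4")
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must be in [0, 1]")
        if self.azimuth_rad is None:
            self.azimuth_rad = self.angle_index * np.pi / N_ANGLES

    @property
    def phase_offset(self) -> float:
        """Uniform 2*pi/5 phase steps."""
        return 2.0 * np.pi * self.phase_index / N_PHASES

    def beam_amplitudes(self) -> Tuple[float, float]:
        """(a0, a1) with mean intensity a0^2 + 2 a1^2 = 1 and focal-plane
        first-harmonic modulation 4 a0 a1 = m."""
        m = self.modulation_depth
        x = 0.5 * (1.0 + math.sqrt(max(1.0 - m * m / 2.0, 0.0)))
        a0 = math.sqrt(x)
        a1 = math.sqrt((1.0 - x) / 2.0)
        return a0, a1


def sim_pattern(p: SIMPattern, config: OpticalConfig,
                shape: Tuple[int, int, int],
                z_planes_nm: Optional[Sequence[float]] = None,
                z_origin_nm: float = 0.0) -> np.ndarray:
    """Three-beam interference intensity on a (z, y, x) grid, mean 1.

    With ``axial`` enabled, the first lateral harmonic is modulated along z
    at the beat frequency between the 0 and +/-1 order axial wavevectors
    (the 3D-SIM axial component); the second harmonic (from the +/-1 order
    pair) is axially constant.  ``z_origin_nm`` shifts the axial modulation,
    which is how the pattern tracks a remotely moved focal plane.
    """
    if p.k_frac > 1.0 + 1e-12:
        raise ValueError(
            f"pattern frequency {p.k_frac} x coherent cutoff exceeds the "
            "excitation cutoff; the +/-1 orders cannot propagate"
        )
    nz, ny, nx = shape
    if z_planes_nm is None:
        z_planes_nm = (np.arange(nz) - (nz - 1) / 2.0) * config.voxel_z_nm
    z = np.asarray(z_planes_nm, dtype=float)
    f_pat = p.k_frac * config.excitation_coherent_cutoff  # 1/nm
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    r = (xx * math.cos(p.azimuth_rad) + yy * math.sin(p.azimuth_rad)) \
        * config.voxel_xy_nm
    psi = 2.0 * np.pi * f_pat * r + p.phase_offset
    a0, a1 = p.beam_amplitudes()
    base = a0 * a0 + 2.0 * a1 * a1  # == 1
    second = 2.0 * a1 * a1 * np.cos(2.0 * psi)
    out = np.empty(shape)
    if p.axial:
        n_s = config.n_sample
        lam = config.lambda_ex_nm
        sin_t = f_pat * lam / n_s
        dkz = (2.0 * np.pi * n_s / lam) * (1.0 - math.sqrt(max(1.0 - sin_t ** 2, 0.0)))
        for i, zi in enumerate(z):
            axial_mod = math.cos(dkz * (zi - z_origin_nm))
            out[i] = base + 4.0 * a0 * a1 * axial_mod * np.cos(psi) + second
    else:
        first = p.modulation_depth * np.cos(psi)
        for i in range(len(z)):
            out[i] = 1.0 + first
    return out


# ---------------------------------------------------------------------------
# Noise and image formation
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Shot + read noise: Poisson photon statistics on top of an expected
    photon image, Gaussian read noise, constant background.  ``photon_budget``
    is the expected peak photon count of a unit-amplitude in-focus emitter in
    an unaberrated system."""

    photon_budget: float = 500.0
    read_noise_e: float = 2.0
    background: float = 5.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.photon_budget, self.read_noise_e, self.background) < 0:
            raise ValueError("noise parameters must be non-negative")

    def apply(self, expected: np.ndarray,
              rng: Optional[np.random.Generator] = None) -> np.ndarray:
        rng = rng if rng is not None else np.random.default_rng(self.seed)
        img = rng.poisson(np.clip(expected + self.background, 0, None)).astype(float)
        if self.read_noise_e > 0:
            img += rng.normal(0.0, self.read_noise_e, size=img.shape)
        return img


@dataclass
class RawSIMStack:
    """Raw SIM frames in canonical (phase, angle, z, channel, y, x) order."""

    data: np.ndarray
    z_positions_nm: np.ndarray
    voxel_xy_nm: float
    voxel_z_nm: float
    metadata: List[dict] = field(default_factory=list)
    order: Tuple[str, ...] = ("phase", "angle", "z", "channel")

    def __post_init__(self) -> None:
        if self.data.ndim != 6:
            raise ValueError("stack must be 6D (phase, angle, z, ch, y, x)")
        if self.data.shape[0] != N_PHASES or self.data.shape[1] != N_ANGLES:
            raise ValueError(
                f"expected {N_PHASES} phases x {N_ANGLES} angles, got "
                f"{self.data.shape[:2]}"
            )

    @property
    def n_frames(self) -> int:
        return int(np.prod(self.data.shape[:4]))


def _psf_slices(config: OpticalConfig, aberration: Optional[ZernikeVector],
                z_offsets_nm: np.ndarray, grid_size: int,
                wavelength_nm: Optional[float] = None) -> np.ndarray:
    pupil = build_pupil(config, aberration, grid_size=grid_size,
                        wavelength_nm=wavelength_nm)
    psf = pupil_to_psf(pupil, z_offsets_nm, normalization="none")
    return psf.intensity


def _ideal_peak(config: OpticalConfig, grid_size: int) -> float:
    """In-focus peak of the unaberrated PSF slice (photon calibration)."""
    return float(_psf_slices(config, None, np.array([0.0]), grid_size).max())


def _conv2_same(img: np.ndarray, kern_fft: np.ndarray, pad: int) -> np.ndarray:
    n = kern_fft.shape[0]
    big = np.zeros((n, n))
    big[:img.shape[0], :img.shape[1]] = img
    out = np.fft.ifft2(np.fft.fft2(big) * kern_fft).real
    return out[:img.shape[0], :img.shape[1]]


class _PlaneRenderer:
    """Renders focal-plane images of a phantom by per-plane 2D FFT
    convolution with slices of the local 3D PSF; caches pupil grids."""

    def __init__(self, phantom: Phantom, config: OpticalConfig):
        self.phantom = phantom
        self.config = config
        nz, ny, nx = phantom.shape
        self.grid = int(2 ** math.ceil(math.log2(2 * max(ny, nx))))
        self._peak0: Optional[float] = None

    def render(self, focal_z_nm: float,
               aberration: Optional[ZernikeVector],
               illumination: Optional[np.ndarray] = None) -> np.ndarray:
        """Expected (noiseless, unit-calibrated) image at one focal plane.

        ``illumination`` is a per-object-plane intensity (same shape as the
        phantom) or None for widefield.
        """
        cfg = self.config
        nz, ny, nx = self.phantom.shape
        obj_z_nm = (np.arange(nz) - (nz - 1) / 2.0) * cfg.voxel_z_nm
        offsets = obj_z_nm - focal_z_nm
        slices = _psf_slices(cfg, aberration, offsets, self.grid)
        if self._peak0 is None:
            self._peak0 = _ideal_peak(cfg, self.grid)
        peak0 = self._peak0
        out = np.zeros((ny, nx))
        for iz in range(nz):
            plane = self.phantom.volume[iz]
            if illumination is not None:
                plane = plane * illumination[iz]
            if not plane.any():
                continue
            kern = np.fft.ifftshift(slices[iz]) / peak0
            kfft = np.fft.fft2(kern)
            out += _conv2_same(plane, kfft, self.grid)
        return out


def render_widefield(phantom: Phantom,
                     aberration: Optional[ZernikeVector],
                     config: OpticalConfig,
                     noise: Optional[NoiseModel] = None,
                     focal_planes_nm: Optional[Sequence[float]] = None,
                     rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Widefield image volume: phantom blurred with PSF(aberration) per
    focal plane, plus (optional) shot and read noise.

    Returns an array (n_focal_planes, ny, nx); default focal planes are the
    phantom's own z planes.  Image values are expected photons when a noise
    model supplies the photon budget, otherwise unit-calibrated intensity
    (1.0 == peak of a unit in-focus emitter without aberration).
    """
    renderer = _PlaneRenderer(phantom, config)
    nz = phantom.shape[0]
    if focal_planes_nm is None:
        focal_planes_nm = (np.arange(nz) - (nz - 1) / 2.0) * config.voxel_z_nm
    frames = []
    for zf in focal_planes_nm:
        img = renderer.render(float(zf), aberration)
        if noise is not None:
            img = noise.apply(img * noise.photon_budget, rng=rng)
        frames.append(img)
    return np.stack(frames)


def _all_patterns(k_frac: float, axial: bool,
                  modulation_depth: float) -> List[SIMPattern]:
    return [SIMPattern(angle_index=a, phase_index=p, k_frac=k_frac,
                       axial=axial, modulation_depth=modulation_depth)
            for a in range(N_ANGLES) for p in range(N_PHASES)]


def render_sim_stack(phantom: Phantom,
                     aberration: Union[ZernikeVector, DepthAberrationModel,
                                       None],
                     config: OpticalConfig,
                     z_positions_nm: Sequence[float],
                     n_channels: int = 1,
                     patterns: Optional[List[SIMPattern]] = None,
                     noise: Optional[NoiseModel] = None,
                     pattern_tracks_focus: bool = True,
                     depth_offset_um: float = 0.0,
                     seed: Optional[int] = None) -> RawSIMStack:
    """Render a full raw 3D-SIM acquisition (5 phases x 3 angles x z x ch).

    Per frame: the phantom is illuminated with the structured pattern,
    blurred with the depth-appropriate PSF, and noise is added.  When
    ``pattern_tracks_focus`` is set, the axial origin of the SI pattern
    follows the focal plane (the synchronized remote-focus behaviour);
    otherwise the pattern stays fixed in sample space.
    """
    z = np.asarray(z_positions_nm, dtype=float)
    if len(z) > 1 and not np.all(np.diff(z) > 0):
        raise ValueError("z positions must be strictly increasing")
    if patterns is None:
        patterns = _all_patterns(0.8, True, 0.9)
    by_idx: Dict[Tuple[int, int], SIMPattern] = {
        (pt.phase_index, pt.angle_index): pt for pt in patterns}
    if len(by_idx) != N_PHASES * N_ANGLES:
        raise ValueError("need one pattern per (phase, angle) combination")
    renderer = _PlaneRenderer(phantom, config)
    nz_obj, ny, nx = phantom.shape
    obj_z_nm = (np.arange(nz_obj) - (nz_obj - 1) / 2.0) * config.voxel_z_nm
    rng = np.random.default_rng(seed if seed is not None
                                else (noise.seed if noise else None))
    data = np.zeros((N_PHASES, N_ANGLES, len(z), n_channels, ny, nx))
    meta: List[dict] = []
    for ic in range(n_channels):
        for iz, zf in enumerate(z):
            depth = depth_offset_um + zf * 1e-3
            if isinstance(aberration, DepthAberrationModel):
                ab = aberration_at_depth(aberration, max(depth, 0.0))
            else:
                ab = aberration
            for ia in range(N_ANGLES):
                for ip in range(N_PHASES):
                    pt = by_idx[(ip, ia)]
                    z_origin = zf if pattern_tracks_focus else 0.0
                    illum = sim_pattern(pt, config, phantom.shape,
                                        z_planes_nm=obj_z_nm,
                                        z_origin_nm=z_origin)
                    img = renderer.render(zf, ab, illumination=illum)
                    if noise is not None:
                        img = noise.apply(img * noise.photon_budget, rng=rng)
                    data[ip, ia, iz, ic] = img
                    meta.append({"phase": ip, "angle": ia, "z_nm": float(zf),
                                 "channel": ic,
                                 "pattern": replace(pt),
                                 "aberration": ab})
    return RawSIMStack(data, z, config.voxel_xy_nm, config.voxel_z_nm, meta)


# ---------------------------------------------------------------------------
# The virtual microscope handle
# ---------------------------------------------------------------------------

class VirtualScope:
    """A stateful virtual microscope the correction loops drive.

    Holds the specimen, the ground-truth aberration (a fixed vector, the
    system-intrinsic term, and/or a depth model), the DM, the noise model
    and the optical configuration.  ``render_frame`` produces one widefield
    frame with the current DM shape applied — the only observable the
    sensorless routine may use — and counts every acquisition.
    """

    def __init__(self,
                 phantom: Phantom,
                 config: Optional[OpticalConfig] = None,
                 system_aberration: Optional[ZernikeVector] = None,
                 sample_aberration: Union[ZernikeVector,
                                          DepthAberrationModel, None] = None,
                 depth_um: float = 0.0,
                 dm: Optional[DMModel] = None,
                 noise: Optional[NoiseModel] = None,
                 seed: Optional[int] = None):
        self.phantom = phantom
        self.config = config or OpticalConfig()
        self.system_aberration = system_aberration
        self.sample_aberration = sample_aberration
        self.depth_um = depth_um
        self.dm = dm or DMModel()
        self.noise = noise
        self.rng = np.random.default_rng(seed)
        self.render_count = 0
        self._renderer = _PlaneRenderer(self.phantom, self.config)

    # -- ground truth --------------------------------------------------------
    def true_aberration(self, focal_z_nm: float = 0.0,
                        imaged_depth_um: Optional[float] = None
                        ) -> ZernikeVector:
        """Aberration experienced when imaging a plane.

        The depth model is evaluated at the depth of the *imaged* plane:
        normally ``depth_um + focal_z``, but a remote-focused acquisition
        images a different plane than the mechanical focus and passes the
        true imaged depth explicitly.
        """
        total = ZernikeVector({})
        if self.system_aberration is not None:
            total = total + self.system_aberration
        sa = self.sample_aberration
        if isinstance(sa, DepthAberrationModel):
            depth = (imaged_depth_um if imaged_depth_um is not None
                     else self.depth_um + focal_z_nm * 1e-3)
            total = total + aberration_at_depth(sa, max(depth, 0.0))
        elif sa is not None:
            total = total + sa
        return total

    # -- acquisition ---------------------------------------------------------
    def render_frame(self, dm_request: Optional[ZernikeVector] = None,
                     focal_z_nm: float = 0.0,
                     illumination: Optional[np.ndarray] = None,
                     imaged_depth_um: Optional[float] = None) -> np.ndarray:
        """One camera frame with the DM set to ``dm_request``."""
        achieved = ZernikeVector({})
        if dm_request is not None:
            achieved, _ = dm_apply(self.dm, dm_request)
        total = self.true_aberration(focal_z_nm, imaged_depth_um) + achieved
        img = self._renderer.render(focal_z_nm, total,
                                    illumination=illumination)
        if self.noise is not None:
            img = self.noise.apply(img * self.noise.photon_budget,
                                   rng=self.rng)
        self.render_count += 1
        return img

    def render_volume(self, focal_planes_nm: Sequence[float],
                      dm_request: Optional[ZernikeVector] = None) -> np.ndarray:
        """A z-stack of widefield frames (mechanical focusing)."""
        return np.stack([self.render_frame(dm_request, float(zf))
                         for zf in focal_planes_nm])
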