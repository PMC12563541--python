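"""Sensorless modal adaptive-optics correction.

Indirect wavefront sensing: each Zernike mode is scanned with a small set of
DM biases (e.g. {-1, -0.5, 0, 0.5, 1} rad) while acquiring a widefield frame
per bias; a noise-corrected Fourier image-quality metric scores each frame; a
Gaussian is fitted to the (bias, metric) points and its mean taken as the
optimal correction for that mode.  System-intrinsic aberrations are measured
once on a sparse bead scene ("system flat") and sample corrections are
applied on top.

The image metric is the windowed spectral power inside an annulus of the
emission passband, minus a noise floor estimated from frequencies beyond the
cutoff where no object signal can exist.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .optics import OpticalConfig
from .scope import VirtualScope
from .zernike import ZernikeVector

__all__ = [
    "BASE_CORRECTION_MODES",
    "BiasScanPlan",
    "MetricConfig",
    "BiasScanResult",
    "CorrectionResult",
    "plan_bias_scan",
    "fourier_metric",
    "fit_gaussian_optimum",
    "correct_plane",
    "system_flat_calibration",
]

#: The base correction set: primary oblique astigmatism (#5) through primary
#: spherical (#11), plus secondary spherical (#22), Noll indexing.
BASE_CORRECTION_MODES: Tuple[int, ...] = (5, 6, 7, 8, 9, 10, 11, 22)

DEFAULT_BIASES: Tuple[float, ...] = (-1.0, -0.5, 0.0, 0.5, 1.0)


@dataclass
class BiasScanPlan:
    """Ordered per-mode bias scan; one image per (mode, bias)."""

    modes: Tuple[int, ...]
    biases: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.modes or not self.biases:
            raise ValueError("modes and biases must be non-empty")
        self.modes = tuple(int(j) for j in self.modes)
        self.biases = tuple(float(b) for b in self.biases)
        if not any(b == 0.0 for b in self.biases):
            raise ValueError("bias list must contain 0 (unbiased reference)")

    @property
    def total_images(self) -> int:
        return len(self.modes) * len(self.biases)


def plan_bias_scan(modes: Sequence[int] = BASE_CORRECTION_MODES,
                   biases: Sequence[float] = DEFAULT_BIASES) -> BiasScanPlan:
    """Build a scan plan; the defaults give the 8-mode x 5-bias, 40-image
    arrangement."""
    return BiasScanPlan(tuple(modes), tuple(biases))


@dataclass
class MetricConfig:
    """Parameters of the Fourier image-quality metric.

    Annulus bounds and the noise band are fractions of the emission
    incoherent cutoff 2*NA/lambda_em.  The noise band must lie entirely
    beyond the cutoff (>= 1).
    """

    annulus_low: float = 0.1
    annulus_high: float = 0.9
    noise_band: Tuple[float, float] = (1.02, 1.35)
    window: str = "hann"
    subtract_noise: bool = True
    normalize_dc: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.annulus_low < self.annulus_high <= 1.0:
            raise ValueError("require 0 < annulus_low < annulus_high <= 1")
        if self.noise_band[0] < 1.0 or self.noise_band[1] <= self.noise_band[0]:
            raise ValueError("noise band must lie beyond the cutoff")


@dataclass
class BiasScanResult:
    """Scan data and fitted optimum for one mode."""

    mode: int
    biases: np.ndarray
    metrics: np.ndarray
    optimum: float
    fit_params: Optional[dict]  # mean, sd, amplitude, offset
    r_squared: float
    converged: bool
    fallback: bool


@dataclass
class CorrectionResult:
    """Outcome of one correction pass over a plane."""

    system_flat: ZernikeVector
    sample_correction: ZernikeVector
    scans: List[BiasScanResult] = field(default_factory=list)
    total_images: int = 0

    @property
    def combined(self) -> ZernikeVector:
        """system flat + sample correction, directly applicable to the DM."""
        return self.system_flat + self.sample_correction


def _window2d(shape: Tuple[int, int], name: str) -> np.ndarray:
    if name == "hann":
        wy = np.hanning(shape[0])
        wx = np.hanning(shape[1])
        return np.outer(wy, wx)
    if name in (None, "none"):
        return np.ones(shape)
    raise ValueError(f"unknown window {name!r}")


def fourier_metric(image: np.ndarray, config: Optional[MetricConfig] = None,
                   optics: Optional[OpticalConfig] = None) -> float:
    """Noise-corrected in-band spectral power of a single frame.

    Windowed 2D power spectrum; total power inside the annulus
    [low, high] * cutoff, minus the annulus-area-scaled mean power of the
    beyond-cutoff noise band; floored at 0.  A constant image scores 0 with
    a warning rather than raising.
    """
    cfg = config or MetricConfig()
    opt = optics or OpticalConfig()
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if np.ptp(img) == 0:
        warnings.warn("constant image; metric is 0", stacklevel=2)
        return 0.0
    win = _window2d(img.shape, cfg.window)
    spec = np.fft.fft2((img - img.mean()) * win)
    power = np.abs(spec) ** 2
    fy = np.fft.fftfreq(img.shape[0], d=opt.voxel_xy_nm)
    fx = np.fft.fftfreq(img.shape[1], d=opt.voxel_xy_nm)
    f_r = np.hypot(fy[:, None], fx[None, :])
    cutoff = opt.emission_cutoff
    annulus = (f_r >= cfg.annulus_low * cutoff) & (f_r <= cfg.annulus_high * cutoff)
    total = float(power[annulus].sum())
    if cfg.normalize_dc:
        dc = float(np.abs(np.fft.fft2(img * win)[0, 0]) ** 2)
        if dc > 0:
            total /= dc
    if cfg.subtract_noise:
        nyq = min(fy.max(), fx.max())
        lo = cfg.noise_band[0] * cutoff
        hi = min(cfg.noise_band[1] * cutoff, 0.98 * nyq * math.sqrt(2))
        band = (f_r >= lo) & (f_r <= hi)
        if band.sum() == 0:
            warnings.warn("noise band empty (cutoff at Nyquist); "
                          "skipping noise subtraction", stacklevel=2)
        else:
            floor = float(power[band].mean())
            if cfg.normalize_dc:
                dc = float(np.abs(np.fft.fft2(img * win)[0, 0]) ** 2)
                if dc > 0:
                    floor /= dc
            total -= floor * int(annulus.sum())
    return max(total, 0.0)


def _gauss(b, amp, mean, sd, offset):
    return offset + amp * np.exp(-0.5 * ((b - mean) / sd) ** 2)


def fit_gaussian_optimum(biases: Sequence[float],
                         metrics: Sequence[float],
                         safety_factor: float = 1.5,
                         r2_threshold: float = 0.5) -> Tuple[float, dict]:
    """Fit Gaussian-plus-offset to (bias, metric) points; the fitted mean is
    the optimal modal correction.

    If the fit fails, has poor quality (R^2 below threshold), or puts the
    mean outside ``safety_factor`` times the scanned range, falls back to
    the bias with the maximum metric and flags it.
    """
    b = np.asarray(biases, dtype=float)
    m = np.asarray(metrics, dtype=float)
    if len(b) < 4:
        raise ValueError("need at least 4 scan points for a Gaussian fit")
    span = b.max() - b.min()
    i_max = int(np.argmax(m))
    fallback_opt = float(b[i_max])
    diag: dict = {"converged": False, "fallback": True, "r_squared": 0.0,
                  "fit_params": None}
    p0 = [max(m.max() - m.min(), 1e-12), float(b[i_max]), span / 3.0,
          float(m.min())]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss, b, m, p0=p0,
                bounds=([0.0, b.min() - span, 1e-3 * span, -np.inf],
                        [np.inf, b.max() + span, 10.0 * span, np.inf]),
                maxfev=5000)
    except (RuntimeError, ValueError):
        return fallback_opt, diag
    resid = m - _gauss(b, *popt)
    ss_tot = float(((m - m.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 0.0
    mean = float(popt[1])
    diag.update(converged=True, r_squared=r2,
                fit_params={"amplitude": float(popt[0]), "mean": mean,
                            "sd": float(popt[2]), "offset": float(popt[3])})
    limit = safety_factor * max(abs(b.min()), abs(b.max()))
    if r2 < r2_threshold or abs(mean) > limit:
        diag["fallback"] = True
        return fallback_opt, diag
    diag["fallback"] = False
    return mean, diag


def correct_plane(scope: VirtualScope,
                  plan: Optional[BiasScanPlan] = None,
                  metric_cfg: Optional[MetricConfig] = None,
                  initial: Optional[ZernikeVector] = None,
                  focal_z_nm: float = 0.0,
                  passes: int = 1) -> CorrectionResult:
    """Run the sensorless correction routine on one focal plane.

    Modes are scanned sequentially (ascending-Noll plan order); each mode's
    fitted optimum is accumulated into the running correction before the
    next mode is scanned.  The stored corrections are the amplitudes applied
    to the DM, so ``combined = system_flat + sample_correction`` can be sent
    to the mirror as-is.  Raises if every mode fell back (metric carried no
    usable signal).
    """
    plan = plan or plan_bias_scan()
    metric_cfg = metric_cfg or MetricConfig()
    flat = initial if initial is not None else ZernikeVector({})
    correction = ZernikeVector({})
    scans: List[BiasScanResult] = []
    n_images = 0
    for _ in range(max(passes, 1)):
        for j in plan.modes:
            metrics = []
            for b in plan.biases:
                request = (flat + correction).with_mode(
                    j, (flat + correction)[j] + b)
                frame = scope.render_frame(request, focal_z_nm=focal_z_nm)
                n_images += 1
                metrics.append(fourier_metric(frame, metric_cfg,
                                              scope.config))
            opt, diag = fit_gaussian_optimum(plan.biases, metrics)
            scans.append(BiasScanResult(
                mode=j, biases=np.asarray(plan.biases),
                metrics=np.asarray(metrics), optimum=opt,
                fit_params=diag["fit_params"], r_squared=diag["r_squared"],
                converged=diag["converged"], fallback=diag["fallback"]))
            correction = correction.with_mode(j, correction[j] + opt)
    if scans and all(s.fallback for s in scans):
        raise RuntimeError(
            "correction unreliable: every mode scan fell back to its "
            "max-metric bias (no usable metric signal)")
    return CorrectionResult(system_flat=flat, sample_correction=correction,
                            scans=scans, total_images=n_images)


def system_flat_calibration(scope: VirtualScope,
                            plan: Optional[BiasScanPlan] = None,
                            metric_cfg: Optional[MetricConfig] = None,
                            passes: int = 1) -> ZernikeVector:
    """Measure the system flat on a sparse-bead scene.

    The scope should carry only system-intrinsic aberration; the returned
    vector is what the DM must apply to null it, to be passed as ``initial``
    to subsequent sample corrections.
    """
    result = correct_plane(scope, plan=plan, metric_cfg=metric_cfg,
                           initial=ZernikeVector({}), passes=passes)
    return result.sample_correction
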