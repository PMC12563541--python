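"""Multi-position aberration correction (MPAC) and DM remote focusing.

MPAC: run the sensorless correction at a few anchor planes (typically top
and bottom of the volume), fit a straight line per Zernike mode against z,
and predict the correction for every section in between — valid because the
dominant depth aberrations (spherical in particular) grow linearly with
imaging depth.

Remote focusing: the axial shift of the focal plane produced by adding the
high-NA refocusing phase ``k n z sqrt(1 - (NA rho / n)^2)`` to the pupil,
realized on the DM as its projection onto Zernike defocus + primary +
secondary spherical (Noll 4, 11, 22).  Calibration renders a bead volume per
commanded shift, localizes the axial PSF peak, and regresses achieved on
commanded shift (precision); a monotone residual correction on the command
axis then supplies accuracy.  Correction and refocus patterns are kept
independent and summed when used together.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.interpolate import PchipInterpolator

from .optics import OpticalConfig
from .scope import VirtualScope
from .zernike import ZernikeVector, noll_to_nm, zernike_eval

__all__ = [
    "MPACTable",
    "RemoteFocusCalib",
    "mpac_fit",
    "mpac_predict",
    "refocus_phase",
    "calibrate_remote_focus",
    "combine_patterns",
    "remote_z_stack",
]

REFOCUS_MODES: Tuple[int, ...] = (4, 11, 22)
EXTENDED_REFOCUS_MODES: Tuple[int, ...] = (4, 11, 22, 37)


# ---------------------------------------------------------------------------
# MPAC
# ---------------------------------------------------------------------------

@dataclass
class MPACTable:
    """Per-mode linear (slope, intercept) fit of corrections against z.

    With exactly two anchors the fit interpolates them exactly; prediction
    is affine in z for every mode.
    """

    slopes: Dict[int, float]       # rad / um
    intercepts: Dict[int, float]   # rad
    anchors: List[Tuple[float, ZernikeVector]]
    residual_rms: Dict[int, float] = field(default_factory=dict)
    reference_wavelength_nm: float = 525.0

    @property
    def z_range_um(self) -> Tuple[float, float]:
        zs = [z for z, _ in self.anchors]
        return (min(zs), max(zs))

    @property
    def modes(self) -> Tuple[int, ...]:
        return tuple(sorted(self.slopes))


def mpac_fit(anchors: Sequence[Tuple[float, ZernikeVector]]) -> MPACTable:
    """Independent least-squares line per mode over the union of anchor
    modes (a mode absent at an anchor counts as 0 there)."""
    anchors = list(anchors)
    if len(anchors) < 2:
        raise ValueError("MPAC needs at least 2 anchor planes")
    zs = np.array([float(z) for z, _ in anchors])
    if np.ptp(zs) == 0 or len(np.unique(zs)) < 2:
        raise ValueError("anchor z positions must be distinct")
    modes = sorted({j for _, v in anchors for j in v})
    ref_wl = anchors[0][1].reference_wavelength_nm
    slopes, intercepts, resid = {}, {}, {}
    for j in modes:
        a = np.array([v[j] for _, v in anchors])
        coef = np.polyfit(zs, a, 1)
        slopes[j] = float(coef[0])
        intercepts[j] = float(coef[1])
        resid[j] = float(np.sqrt(np.mean((np.polyval(coef, zs) - a) ** 2)))
    return MPACTable(slopes, intercepts, anchors, resid, ref_wl)


def mpac_predict(table: MPACTable, z_um: float,
                 warn_extrapolation: bool = True) -> ZernikeVector:
    """Affine per-mode evaluation at depth ``z_um``; extrapolation beyond
    the anchor span is allowed but warned about."""
    lo, hi = table.z_range_um
    if warn_extrapolation and not (lo - 1e-9 <= z_um <= hi + 1e-9):
        warnings.warn(
            f"MPAC prediction at z={z_um} um extrapolates beyond the anchor "
            f"span [{lo}, {hi}] um", stacklevel=2)
    coeffs = {j: table.slopes[j] * z_um + table.intercepts[j]
              for j in table.slopes}
    return ZernikeVector(coeffs, table.reference_wavelength_nm)


# ---------------------------------------------------------------------------
# Remote focusing
# ---------------------------------------------------------------------------

def refocus_phase(shift_um: float, config: OpticalConfig,
                  modes: Sequence[int] = REFOCUS_MODES,
                  max_shift_um: float = 10.0,
                  n_quad: int = 4096,
                  wavelength_nm: Optional[float] = None
                  ) -> Tuple[ZernikeVector, float]:
    """DM pattern that moves the focal plane by ``shift_um``.

    The exact high-NA defocus phase is projected (radial quadrature) onto
    the rotationally symmetric Zernike modes in ``modes``; the returned
    residual is the RMS (radians, piston removed) of the phase the chosen
    modes cannot represent — reported, never silently dropped.  Odd in the
    shift: refocus(-z) == -refocus(z).
    """
    if abs(shift_um) > max_shift_um + 1e-12:
        raise ValueError(
            f"requested shift {shift_um} um exceeds the DM range "
            f"+/-{max_shift_um} um")
    lam = float(wavelength_nm or config.lambda_em_nm)
    for j in modes:
        n, m = noll_to_nm(j)
        if m != 0:
            raise ValueError(f"refocus basis must be rotationally symmetric, "
                             f"mode {j} has m={m}")
    z_nm = shift_um * 1e3
    k = 2.0 * math.pi * config.n_immersion / lam
    # midpoint rule in rho^2 (uniform measure on the disk)
    u = (np.arange(n_quad) + 0.5) / n_quad
    rho = np.sqrt(u)
    sin2 = np.clip((config.na * rho / config.n_immersion) ** 2, 0, 1)
    # sign: cancel the renderer's axial phase at the target plane, so a
    # positive shift images the object plane at +z
    phi = -k * z_nm * np.sqrt(1.0 - sin2)
    piston = float(phi.mean())
    coeffs: Dict[int, float] = {}
    resid = phi - piston
    for j in modes:
        zj = zernike_eval(j, rho, np.zeros_like(rho))
        a = float(np.mean(phi * zj))
        coeffs[j] = a
        resid = resid - a * zj
    residual_rms = float(np.sqrt(np.mean(resid ** 2)))
    vec = ZernikeVector({j: a for j, a in coeffs.items() if a != 0.0},
                        reference_wavelength_nm=lam)
    vec.meta = {"kind": "refocus", "shift_um": shift_um,
                "residual_rms_rad": residual_rms}
    return vec, residual_rms


@dataclass
class RemoteFocusCalib:
    """Two-step remote-focus calibration.

    Step 1 (precision): linear regression of achieved focal shift on
    commanded shift.  Step 2 (accuracy): a monotone cubic correction on the
    command axis absorbs the residuals, so ``command_for`` returns the
    command that lands on a target plane to within ``tolerance_um``.
    """

    commanded_um: np.ndarray
    achieved_um: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    validated_range_um: Tuple[float, float]
    tolerance_um: float
    _inverse: Optional[PchipInterpolator] = None

    def predict_shift(self, command_um: float) -> float:
        """Linear (step-1) model of the achieved shift."""
        return self.slope * command_um + self.intercept

    def command_for(self, target_shift_um: float) -> float:
        """Accurate (step-2) command for a target focal shift."""
        lo, hi = self.validated_range_um
        if not lo - 1e-9 <= target_shift_um <= hi + 1e-9:
            raise ValueError(
                f"target {target_shift_um} um outside validated range "
                f"[{lo:.2f}, {hi:.2f}] um")
        if self._inverse is not None:
            return float(self._inverse(target_shift_um))
        return (target_shift_um - self.intercept) / self.slope


def _axial_peak_um(profile: np.ndarray, z_planes_nm: np.ndarray) -> float:
    """Center-of-mass within +/-3 planes of the max, then parabolic
    refinement; ties break toward smaller z."""
    i = int(np.argmax(profile))
    lo, hi = max(i - 3, 0), min(i + 3, len(profile) - 1)
    w = profile[lo:hi + 1] - profile[lo:hi + 1].min()
    if w.sum() > 0:
        com = float(np.sum(np.arange(lo, hi + 1) * w) / w.sum())
        i = int(round(com))
        if abs(com - i) == 0.5:  # tie: smaller z
            i = int(math.floor(com))
    i = min(max(i, 1), len(profile) - 2)
    y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
    denom = (y0 - 2 * y1 + y2)
    frac = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    frac = float(np.clip(frac, -0.5, 0.5))
    step = float(np.mean(np.diff(z_planes_nm)))
    return (z_planes_nm[i] + frac * step) * 1e-3


def calibrate_remote_focus(scope: VirtualScope,
                           command_shifts_um: Sequence[float],
                           modes: Sequence[int] = REFOCUS_MODES,
                           tolerance_um: float = 0.1,
                           r2_min: float = 0.99,
                           z_pad_um: float = 2.0,
                           max_shift_um: float = 10.0) -> RemoteFocusCalib:
    """Calibrate commanded-vs-achieved focal shift on a bead scene.

    For each commanded shift, the refocus pattern is applied through the
    scope's DM, a bead volume is rendered with mechanical focus fixed, and
    the axial PSF peak is localized with sub-plane precision.  Raises if the
    linear fit over the requested range has R^2 below ``r2_min``, reporting
    the usable sub-range.
    """
    cmds = np.sort(np.asarray(command_shifts_um, dtype=float))
    if len(cmds) < 3:
        raise ValueError("need at least 3 command amplitudes")
    span = max(abs(cmds.min()), abs(cmds.max())) + z_pad_um
    step = scope.config.voxel_z_nm
    n_half = int(math.ceil(span * 1e3 / step))
    z_planes = np.arange(-n_half, n_half + 1) * step
    achieved = np.empty_like(cmds)
    for i, c in enumerate(cmds):
        pattern, _ = refocus_phase(c, scope.config, modes=modes,
                                   max_shift_um=max_shift_um)
        vol = scope.render_volume(z_planes, dm_request=pattern)
        profile = vol.max(axis=(1, 2))
        # remote shift +z moves the sharp plane to mechanical focus -z' such
        # that the bead is in focus where refocus cancels mechanical defocus
        achieved[i] = -_axial_peak_um(profile, z_planes)
    coef = np.polyfit(cmds, achieved, 1)
    pred = np.polyval(coef, cmds)
    ss_res = float(((achieved - pred) ** 2).sum())
    ss_tot = float(((achieved - achieved.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < r2_min:
        # shrink symmetrically to report a usable sub-range
        usable = None
        for k in range(1, (len(cmds) - 2) // 2 + 1):
            sub = slice(k, len(cmds) - k)
            c2 = np.polyfit(cmds[sub], achieved[sub], 1)
            p2 = np.polyval(c2, cmds[sub])
            sst = float(((achieved[sub] - achieved[sub].mean()) ** 2).sum())
            if sst > 0 and 1 - ((achieved[sub] - p2) ** 2).sum() / sst >= r2_min:
                usable = (cmds[sub][0], cmds[sub][-1])
                break
        raise RuntimeError(
            f"remote-focus calibration failed: R^2={r2:.4f} < {r2_min} over "
            f"[{cmds[0]}, {cmds[-1]}] um"
            + (f"; usable sub-range ~[{usable[0]}, {usable[1]}] um"
               if usable else ""))
    # step 2: monotone cubic command-for-target mapping from the raw pairs
    order = np.argsort(achieved)
    ach_s, cmd_s = achieved[order], cmds[order]
    keep = np.concatenate([[True], np.diff(ach_s) > 1e-9])
    inverse = PchipInterpolator(ach_s[keep], cmd_s[keep], extrapolate=True)
    validated = (float(ach_s.min()), float(ach_s.max()))
    return RemoteFocusCalib(cmds, achieved, float(coef[0]), float(coef[1]),
                            r2, validated, tolerance_um, inverse)


def combine_patterns(correction: ZernikeVector,
                     refocus: ZernikeVector) -> ZernikeVector:
    """Sum the independent correction and refocus DM patterns, retaining
    the provenance of each addend."""
    combined = correction + refocus
    combined.meta = {"correction": correction, "refocus": refocus}
    return combined


def remote_z_stack(scope: VirtualScope,
                   z_targets_um: Sequence[float],
                   calib: RemoteFocusCalib,
                   mpac_table: Optional[MPACTable] = None,
                   refocus_modes: Sequence[int] = REFOCUS_MODES,
                   max_shift_um: float = 10.0) -> np.ndarray:
    """Acquire a z-stack by DM refocusing instead of stage motion.

    Per plane: the accurate refocus command for the target plane is combined
    with the MPAC-predicted correction for that depth; the mechanical focus
    never moves.  Output layout is identical to a mechanical z-stack.
    Raises listing any planes outside the calibrated range.
    """
    z = np.asarray(z_targets_um, dtype=float)
    lo, hi = calib.validated_range_um
    bad = [float(t) for t in z if not lo - 1e-9 <= t <= hi + 1e-9]
    if bad:
        raise ValueError(
            f"z targets outside calibrated range [{lo:.2f}, {hi:.2f}] um: "
            f"{bad}")
    frames = []
    for t in z:
        cmd = calib.command_for(float(t))
        pattern, _ = refocus_phase(cmd, scope.config, modes=refocus_modes,
                                   max_shift_um=max_shift_um)
        if mpac_table is not None:
            pattern = combine_patterns(
                mpac_predict(mpac_table, float(t), warn_extrapolation=False),
                pattern)
        frames.append(scope.render_frame(
            pattern, focal_z_nm=0.0,
            imaged_depth_um=scope.depth_um + float(t)))
    return np.stack(frames)
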