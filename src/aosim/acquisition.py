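"""Acquisition planning and bookkeeping.

Frame-count arithmetic, ordered frame descriptors, z-range computation, and
per-frame device-state (trigger) tables that mirror a real-time TTL-driven
acquisition: all DM patterns are precomputed, deduplicated per z plane, and
referenced by id from the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .mpac import (MPACTable, RemoteFocusCalib, combine_patterns,
                   mpac_predict, refocus_phase)
from .zernike import ZernikeVector

__all__ = [
    "AcquisitionPlan",
    "plan_acquisition",
    "z_span",
    "build_trigger_table",
    "volume_duration",
]

CANONICAL_ORDER: Tuple[str, ...] = ("phase", "angle", "z", "channel")


@dataclass
class AcquisitionPlan:
    """One 3D volume acquisition.

    SIM mode always carries the full 5-phase x 3-angle complement; widefield
    is one frame per (z, channel).  ``ordering`` lists dimensions from
    fastest- to slowest-varying (default: phase fastest, then angle, z,
    channel — phase stepping is the cheapest state change).
    """

    n_channels: int
    n_z: int
    z_step_nm: float
    mode: str = "sim"
    focus: str = "mechanical"
    n_phases: int = 5
    n_angles: int = 3
    ordering: Tuple[str, ...] = CANONICAL_ORDER
    slm_settle_ms: float = 20.0
    camera_readout_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_z < 1:
            raise ValueError("channel and z counts must be positive")
        if self.z_step_nm <= 0:
            raise ValueError("z step must be positive")
        if self.mode not in ("sim", "widefield"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.focus not in ("mechanical", "remote"):
            raise ValueError(f"unknown focus mode {self.focus!r}")
        if sorted(self.ordering) != sorted(CANONICAL_ORDER):
            raise ValueError(
                f"ordering must be a permutation of {CANONICAL_ORDER}")

    @property
    def total_frames(self) -> int:
        per_z = (self.n_phases * self.n_angles if self.mode == "sim" else 1)
        return per_z * self.n_channels * self.n_z

    @property
    def z_positions_nm(self) -> np.ndarray:
        return (np.arange(self.n_z) - (self.n_z - 1) / 2.0) * self.z_step_nm

    def frame_descriptors(self) -> List[dict]:
        """Ordered per-frame (phase, angle, z, channel) descriptors."""
        extents = {
            "phase": self.n_phases if self.mode == "sim" else 1,
            "angle": self.n_angles if self.mode == "sim" else 1,
            "z": self.n_z,
            "channel": self.n_channels,
        }
        # ordering is fastest-first; itertools.product varies the last
        # element fastest, so iterate slowest-first reversed
        dims = tuple(reversed(self.ordering))
        z_nm = self.z_positions_nm
        out = []
        for combo in product(*[range(extents[d]) for d in dims]):
            idx = dict(zip(dims, combo))
            out.append({
                "phase": idx["phase"], "angle": idx["angle"],
                "z": idx["z"], "channel": idx["channel"],
                "z_nm": float(z_nm[idx["z"]]),
            })
        return out


def plan_acquisition(n_channels: int, n_z: int, z_step_nm: float = 125.0,
                     mode: str = "sim", focus: str = "mechanical",
                     ordering: Optional[Tuple[str, ...]] = None
                     ) -> AcquisitionPlan:
    """Build an acquisition plan with the fixed 5x3 SIM complement."""
    return AcquisitionPlan(n_channels=n_channels, n_z=n_z,
                           z_step_nm=z_step_nm, mode=mode, focus=focus,
                           ordering=ordering or CANONICAL_ORDER)


def z_span(n_sections: int, step_nm: float) -> float:
    """Axial span (n - 1) * step of a z-stack, in micrometres."""
    if n_sections < 1:
        raise ValueError("need at least one section")
    if step_nm <= 0:
        raise ValueError("step must be positive")
    return (n_sections - 1) * step_nm * 1e-3


def build_trigger_table(plan: AcquisitionPlan,
                        mpac_table: Optional[MPACTable] = None,
                        calib: Optional[RemoteFocusCalib] = None,
                        config=None,
                        ) -> Tuple[pd.DataFrame, List[ZernikeVector]]:
    """Per-frame device states plus the precomputed DM pattern set.

    One row per frame; ``dm_pattern_id`` indexes the returned pattern list,
    deduplicated per z plane (remote focus and/or MPAC make the DM state a
    pure function of z).  Remote focus requires a calibration; z targets
    outside its validated range raise.
    """
    if plan.focus == "remote" and calib is None:
        raise ValueError("remote-focus plans require a RemoteFocusCalib")
    z_nm = plan.z_positions_nm
    patterns: List[ZernikeVector] = []
    dm_id_by_z: dict = {}
    for iz, znm in enumerate(z_nm):
        z_um = znm * 1e-3
        pat = ZernikeVector({})
        if plan.focus == "remote":
            lo, hi = calib.validated_range_um
            if not lo - 1e-9 <= z_um <= hi + 1e-9:
                raise ValueError(
                    f"z target {z_um:.3f} um outside calibrated range "
                    f"[{lo:.2f}, {hi:.2f}] um")
            pat = refocus_phase(calib.command_for(z_um),
                                config or _default_cfg())[0]
        if mpac_table is not None:
            pat = combine_patterns(
                mpac_predict(mpac_table, z_um, warn_extrapolation=False),
                pat)
        key = tuple(sorted(pat.as_dict().items()))
        if key not in dm_id_by_z:
            dm_id_by_z[key] = len(patterns)
            patterns.append(pat)
        dm_id_by_z[iz] = dm_id_by_z[key]
    rows = []
    for i, d in enumerate(plan.frame_descriptors()):
        rows.append({
            "frame": i,
            "slm_pattern": (d["angle"] * plan.n_phases + d["phase"]
                            if plan.mode == "sim" else -1),
            "polarization_state": d["angle"] if plan.mode == "sim" else -1,
            "laser_channel": d["channel"],
            "camera": d["channel"],
            "dm_pattern_id": dm_id_by_z[d["z"]],
            "z_target_nm": d["z_nm"],
        })
    return pd.DataFrame(rows), patterns


def _default_cfg():
    from .optics import OpticalConfig
    return OpticalConfig()


def volume_duration(plan: AcquisitionPlan, frame_rate_fps: float) -> float:
    """Seconds per volume at a sustained frame rate."""
    if frame_rate_fps <= 0:
        raise ValueError("frame rate must be positive")
    return plan.total_frames / frame_rate_fps
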