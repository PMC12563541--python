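"""File I/O, run configuration, fixtures and the pipeline driver.

Raw SIM stacks are written as multi-page 32-bit TIFF with the pages flattened
in a declared dimension order (canonical: phase fastest, then angle, z,
channel) plus a YAML sidecar recording shapes, order, voxel sizes and z
positions; the reader restores canonical order and refuses shape mismatches
loudly.  Configs, correction vectors and calibration tables are plain YAML
with units spelled out in the key names, so a run is reproducible from its
persisted RunConfig alone.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import tifffile
import yaml

from .mpac import MPACTable, RemoteFocusCalib
from .optics import OpticalConfig
from .scope import (DepthAberrationModel, NoiseModel, Phantom, RawSIMStack,
                    make_bead_phantom, make_filament_phantom,
                    make_mosaic_phantom)
from .zernike import ZernikeVector

__all__ = [
    "write_stack",
    "read_stack",
    "write_volume",
    "read_volume",
    "save_config",
    "load_config",
    "save_zernike",
    "load_zernike",
    "make_fixture",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger("aosim")

CANONICAL = ("phase", "angle", "z", "channel")
FIXTURE_NAMES = ("bead_slide", "deep_bead_slide", "filament_cell",
                 "mosaic_brain")


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def write_stack(path: Union[str, Path], stack: RawSIMStack,
                order: Sequence[str] = CANONICAL) -> None:
    """Write a raw SIM stack as multi-page float32 TIFF + YAML sidecar."""
    path = Path(path)
    order = tuple(order)
    if sorted(order) != sorted(CANONICAL):
        raise ValueError(f"order must be a permutation of {CANONICAL}")
    # canonical data axes: (phase, angle, z, channel, y, x); page-flatten with
    # the declared order fastest-first -> slowest axis leftmost in the array
    axes = tuple(CANONICAL.index(d) for d in reversed(order)) + (4, 5)
    arr = np.transpose(stack.data, axes)
    pages = arr.reshape(-1, *arr.shape[-2:]).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = {
        "order_fastest_first": list(order),
        "extents": {d: int(stack.data.shape[CANONICAL.index(d)])
                    for d in CANONICAL},
        "voxel_xy_nm": float(stack.voxel_xy_nm),
        "voxel_z_nm": float(stack.voxel_z_nm),
        "z_positions_nm": [float(z) for z in stack.z_positions_nm],
    }
    Path(str(path) + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_stack(path: Union[str, Path],
               declared_order: Optional[Sequence[str]] = None,
               extents: Optional[dict] = None) -> RawSIMStack:
    """Read a stack written by :func:`write_stack`, restoring canonical
    (phase, angle, z, channel) order.

    Without a sidecar, ``declared_order`` and ``extents`` must be supplied;
    a dimension mismatch raises an error printing both shapes.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    sidecar_path = Path(str(path) + ".yaml")
    meta = (yaml.safe_load(sidecar_path.read_text())
            if sidecar_path.exists() else {})
    order = tuple(declared_order or meta.get("order_fastest_first", CANONICAL))
    ext = extents or meta.get("extents")
    if ext is None:
        raise ValueError("no sidecar found; supply declared_order and extents")
    expect = int(np.prod([ext[d] for d in CANONICAL]))
    if pages.shape[0] != expect:
        raise ValueError(
            f"dimension mismatch: file has {pages.shape[0]} pages of "
            f"{pages.shape[1:]}, declared extents {dict(ext)} imply "
            f"{expect} pages")
    shape = tuple(ext[d] for d in reversed(order)) + pages.shape[1:]
    arr = pages.reshape(shape)
    # invert the transpose used by write_stack
    axes = tuple(CANONICAL.index(d) for d in reversed(order)) + (4, 5)
    inv = np.argsort(axes)
    data = np.transpose(arr, inv)
    z = np.asarray(meta.get("z_positions_nm",
                            np.arange(ext["z"]) * 125.0), dtype=float)
    return RawSIMStack(data.astype(float), z,
                       float(meta.get("voxel_xy_nm", 100.0)),
                       float(meta.get("voxel_z_nm", 125.0)))


def write_volume(path: Union[str, Path], volume: np.ndarray,
                 voxel_xy_nm: float = 100.0,
                 voxel_z_nm: float = 125.0) -> None:
    """Write a plain image volume (z, y, x) as float32 TIFF with voxel-size
    resolution tags."""
    vol = np.asarray(volume, dtype=np.float32)
    if vol.ndim == 2:
        vol = vol[None]
    tifffile.imwrite(
        Path(path), vol,
        resolution=(1e7 / voxel_xy_nm, 1e7 / voxel_xy_nm),
        metadata={"spacing": voxel_z_nm * 1e-3, "unit": "um",
                  "axes": "ZYX"},
        imagej=True)


def read_volume(path: Union[str, Path]) -> np.ndarray:
    vol = tifffile.imread(Path(path))
    if vol.ndim == 2:
        vol = vol[None]
    return np.asarray(vol, dtype=float)


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------

def save_config(path: Union[str, Path], config: OpticalConfig) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config)))


def load_config(path: Union[str, Path]) -> OpticalConfig:
    return OpticalConfig(**yaml.safe_load(Path(path).read_text()))


def save_zernike(path: Union[str, Path], vec: ZernikeVector) -> None:
    Path(path).write_text(yaml.safe_dump({
        "reference_wavelength_nm": vec.reference_wavelength_nm,
        "coefficients_rad": {int(j): float(vec[j]) for j in vec},
    }))


def load_zernike(path: Union[str, Path]) -> ZernikeVector:
    d = yaml.safe_load(Path(path).read_text())
    return ZernikeVector({int(j): float(a)
                          for j, a in d["coefficients_rad"].items()},
                         float(d["reference_wavelength_nm"]))


def save_mpac(path: Union[str, Path], table: MPACTable) -> None:
    Path(path).write_text(yaml.safe_dump({
        "slopes_rad_per_um": {int(j): float(v)
                              for j, v in table.slopes.items()},
        "intercepts_rad": {int(j): float(v)
                           for j, v in table.intercepts.items()},
        "anchor_z_um": [float(z) for z, _ in table.anchors],
        "reference_wavelength_nm": table.reference_wavelength_nm,
    }))


def save_remote_calib(path: Union[str, Path], calib: RemoteFocusCalib) -> None:
    Path(path).write_text(yaml.safe_dump({
        "commanded_um": [float(c) for c in calib.commanded_um],
        "achieved_um": [float(a) for a in calib.achieved_um],
        "slope_um_per_um": float(calib.slope),
        "intercept_um": float(calib.intercept),
        "r_squared": float(calib.r_squared),
        "validated_range_um": [float(v) for v in calib.validated_range_um],
        "tolerance_um": float(calib.tolerance_um),
    }))


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def _fixture_scene(name: str, seed: int,
                   config: OpticalConfig) -> Tuple[Phantom, dict]:
    if name == "bead_slide":
        ph = make_bead_phantom(12, diameter_nm=100.0, fov=(1, 128, 128),
                               min_separation_nm=1500.0, seed=seed,
                               config=config)
        extra = {"depth_um": 0.0, "aberration": None}
    elif name == "deep_bead_slide":
        # bead layer under a thick specimen; spherical grows with depth
        ph = make_bead_phantom(12, diameter_nm=100.0, fov=(1, 128, 128),
                               min_separation_nm=1500.0, seed=seed,
                               config=config)
        extra = {"depth_um": 130.0,
                 "aberration": {"slopes_rad_per_um": {11: 0.01, 22: 0.003},
                                "offsets_rad": {}}}
    elif name == "filament_cell":
        ph = make_filament_phantom(6, width_nm=100.0, curvature_scale=0.25,
                                   fov=(1, 128, 128), seed=seed,
                                   config=config)
        extra = {"depth_um": 5.0, "aberration": None}
    elif name == "mosaic_brain":
        ph = make_mosaic_phantom(25, membrane_width_nm=150.0,
                                 fov=(1, 128, 128), seed=seed, config=config)
        extra = {"depth_um": 30.0,
                 "aberration": {"slopes_rad_per_um": {11: 0.01},
                                "offsets_rad": {}}}
    else:
        raise ValueError(
            f"unknown fixture {name!r}; choices: {', '.join(FIXTURE_NAMES)}")
    return ph, extra


def make_fixture(name: str, seed: int, outdir: Union[str, Path]) -> Path:
    """Write a canonical seeded scene bundle (phantom TIFF + config YAML +
    manifest) to ``outdir``; deterministic for a given (name, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = OpticalConfig()
    phantom, extra = _fixture_scene(name, seed, config)
    write_volume(outdir / "phantom.tif", phantom.volume,
                 config.voxel_xy_nm, config.voxel_z_nm)
    save_config(outdir / "optics.yaml", config)
    manifest = {
        "name": name, "seed": int(seed), "kind": phantom.kind,
        "shape": list(phantom.shape),
        "voxel_xy_nm": config.voxel_xy_nm,
        "voxel_z_nm": config.voxel_z_nm,
        "volume_sum": float(phantom.volume.sum()),
        **extra,
    }
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return outdir


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Fully serializable description of one simulate/correct/acquire/analyze
    run; a run is reproducible from this object alone."""

    scene: str = "bead_slide"
    seed: int = 0
    out_dir: str = "aosim_run"
    correct: bool = True
    modes: Tuple[int, ...] = (5, 6, 7, 8, 9, 10, 11, 22)
    biases_rad: Tuple[float, ...] = (-1.0, -0.5, 0.0, 0.5, 1.0)
    injected_aberration_rad: dict = field(default_factory=lambda: {11: 0.8})
    photon_budget: float = 500.0
    read_noise_e: float = 2.0
    background: float = 5.0
    n_z: int = 1
    z_step_nm: float = 125.0

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = asdict(self)
        d["modes"] = list(self.modes)
        d["biases_rad"] = list(self.biases_rad)
        d["injected_aberration_rad"] = {
            int(j): float(a) for j, a in self.injected_aberration_rad.items()}
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["modes"] = tuple(d.get("modes", cls.modes))
        d["biases_rad"] = tuple(d.get("biases_rad", cls.biases_rad))
        d["injected_aberration_rad"] = {
            int(j): float(a)
            for j, a in d.get("injected_aberration_rad", {}).items()}
        return cls(**d)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate a scene, optionally run the sensorless correction, acquire a
    corrected and an uncorrected frame, and report Strehl-proxy statistics.

    Persists every intermediate (config, correction vectors, frames) under
    ``config.out_dir`` and returns a result dictionary.
    """
    from .optics import build_pupil, pupil_to_psf, strehl
    from .scope import DMModel, VirtualScope
    from .sensorless import MetricConfig, correct_plane, plan_bias_scan

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    opt = OpticalConfig()
    stage = "simulate"
    results: dict = {"stages": []}
    try:
        phantom, extra = _fixture_scene(config.scene, config.seed, opt)
        injected = ZernikeVector({int(j): float(a) for j, a
                                  in config.injected_aberration_rad.items()})
        noise = NoiseModel(config.photon_budget, config.read_noise_e,
                           config.background, seed=config.seed)
        scope = VirtualScope(phantom, opt, sample_aberration=injected,
                             noise=noise, seed=config.seed)
        write_volume(out / "uncorrected.tif",
                     scope.render_frame(None), opt.voxel_xy_nm)
        results["stages"].append(stage)
        corrected_vec = ZernikeVector({})
        if config.correct:
            stage = "correct"
            plan = plan_bias_scan(config.modes, config.biases_rad)
            res = correct_plane(scope, plan, MetricConfig())
            corrected_vec = res.sample_correction
            save_zernike(out / "correction.yaml", corrected_vec)
            results["correction_rad"] = {int(j): float(corrected_vec[j])
                                         for j in corrected_vec}
            results["images_acquired"] = res.total_images
            results["stages"].append(stage)
        stage = "acquire"
        write_volume(out / "corrected.tif",
                     scope.render_frame(corrected_vec), opt.voxel_xy_nm)
        results["stages"].append(stage)
        stage = "analyze"
        z_pl = np.arange(-8, 9) * opt.voxel_z_nm
        psf_ideal = pupil_to_psf(build_pupil(opt, None, grid_size=128), z_pl)
        psf_ab = pupil_to_psf(build_pupil(opt, injected, grid_size=128), z_pl)
        psf_corr = pupil_to_psf(
            build_pupil(opt, injected + corrected_vec, grid_size=128), z_pl)
        results["strehl_uncorrected"] = strehl(psf_ab, psf_ideal)
        results["strehl_corrected"] = strehl(psf_corr, psf_ideal)
        results["stages"].append(stage)
    except Exception:
        log.exception("pipeline aborted in stage %r (partials persisted in %s)",
                      stage, out)
        raise
    (out / "results.yaml").write_text(yaml.safe_dump(results))
    log.info("pipeline complete: %s", results)
    return results
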