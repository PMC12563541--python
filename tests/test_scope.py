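import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aosim import (DMModel, DepthAberrationModel, NoiseModel, OpticalConfig,
                   Phantom, SIMPattern, ZernikeVector, aberration_at_depth,
                   dm_apply, make_bead_phantom, make_filament_phantom,
                   make_mosaic_phantom, render_sim_stack, render_widefield,
                   sim_pattern)
from aosim.scope import RawSIMStack, VirtualScope


# --- phantoms ---------------------------------------------------------------

def test_single_bead_centered(config):
    ph = make_bead_phantom(1, fov=(1, 64, 64), seed=0, config=config)
    com = np.array(np.unravel_index(ph.volume.argmax(), ph.volume.shape))
    assert tuple(com[1:]) == (31, 31) or tuple(com[1:]) == (32, 32)


@pytest.mark.parametrize("maker,kw", [
    (make_bead_phantom, dict(n_beads=6, fov=(1, 96, 96),
                             min_separation_nm=1200.0)),
    (make_filament_phantom, dict(n_filaments=3, fov=(1, 96, 96))),
    (make_mosaic_phantom, dict(n_cells=12, fov=(1, 96, 96))),
])
def test_phantom_seeded_determinism(config, maker, kw):
    a = maker(seed=7, config=config, **kw)
    b = maker(seed=7, config=config, **kw)
    assert np.array_equal(a.volume, b.volume)
    c = maker(seed=8, config=config, **kw)
    assert not np.array_equal(a.volume, c.volume)
    assert a.volume.min() >= 0


def test_bead_packing_infeasible_raises(config):
    with pytest.raises(RuntimeError):
        make_bead_phantom(50, fov=(1, 32, 32), min_separation_nm=2000.0,
                          seed=0, config=config)


def test_straight_filaments_with_zero_curvature(config):
    ph = make_filament_phantom(1, curvature_scale=0.0, fov=(1, 96, 96),
                               seed=3, config=config)
    ys, xs = np.nonzero(ph.volume[0] > 0.5)
    # all bright points lie on one line: collinearity via tiny residual
    if len(xs) > 10 and np.ptp(xs) > 5:
        resid = np.polyfit(xs, ys, 1, full=True)[1]
        assert float(resid[0]) / len(xs) < 0.5


# --- depth model ------------------------------------------------------------

def test_depth_model_affine_evaluation():
    m = DepthAberrationModel(slopes={11: 0.05}, offsets={6: 0.1})
    assert aberration_at_depth(m, 0.0)[6] == 0.1
    assert aberration_at_depth(m, 0.0)[11] == 0.0
    v = aberration_at_depth(m, 10.0)
    assert v[11] == pytest.approx(0.5)
    # affine: midpoint is the mean
    a, b = aberration_at_depth(m, 2.0), aberration_at_depth(m, 6.0)
    mid = aberration_at_depth(m, 4.0)
    assert mid[11] == pytest.approx(0.5 * (a[11] + b[11]))


def test_depth_model_perturbation_seeded():
    kw = dict(slopes={11: 0.05}, perturb_modes=(12, 13), perturb_sd=0.02)
    a = DepthAberrationModel(seed=5, **kw)
    b = DepthAberrationModel(seed=5, **kw)
    c = DepthAberrationModel(seed=6, **kw)
    assert aberration_at_depth(a, 7.0).as_dict() == \
        aberration_at_depth(b, 7.0).as_dict()
    assert aberration_at_depth(a, 7.0).as_dict() != \
        aberration_at_depth(c, 7.0).as_dict()
    with pytest.raises(ValueError):
        aberration_at_depth(a, -1.0)


# --- deformable mirror ------------------------------------------------------

def test_ideal_dm_is_identity():
    req = ZernikeVector({5: 0.4, 11: -0.7})
    ach, rep = dm_apply(DMModel(), req)
    assert ach.as_dict() == req.as_dict()
    assert len(rep["uncorrectable"]) == 0


def test_dm_uncorrectable_mode_reported():
    req = ZernikeVector({37: 1.0})
    ach, rep = dm_apply(DMModel(correctable_modes=tuple(range(2, 23))), req)
    assert len(ach) == 0
    assert rep["uncorrectable"][37] == 1.0


def test_dm_fidelity_and_clip():
    dm = DMModel(fidelity=0.9, clip_rad=0.5)
    ach, rep = dm_apply(dm, ZernikeVector({11: 1.0}))
    assert ach[11] == pytest.approx(0.45)  # clipped to 0.5, then x0.9
    assert rep["clipped_modes"] == [11]


def test_dm_creep_closed_form():
    dm = DMModel(creep_amplitude=0.05, creep_tau_s=10.0)
    req = ZernikeVector({4: 1.0})
    at0, _ = dm_apply(dm, req, t_s=0.0)
    at_inf, _ = dm_apply(dm, req, t_s=1e9)
    assert at0[4] == pytest.approx(1.0)
    assert at_inf[4] - at0[4] == pytest.approx(0.05)


# --- SIM patterns -----------------------------------------------------------

def test_pattern_zero_depth_is_uniform(config):
    p = SIMPattern(modulation_depth=0.0)
    vol = sim_pattern(p, config, (3, 32, 32))
    assert np.allclose(vol, 1.0, atol=1e-12)


@pytest.mark.parametrize("angle", [0, 1, 2])
@pytest.mark.parametrize("k_frac", [0.5, 0.8, 1.0])
def test_phase_sum_uniformity(config, angle, k_frac):
    """Summing the five phase steps cancels both pattern harmonics exactly
    (roots-of-unity cancellation) for every angle and frequency."""
    total = sum(
        sim_pattern(SIMPattern(angle_index=angle, phase_index=ph,
                               k_frac=k_frac, modulation_depth=0.9),
                    config, (3, 32, 32))
        for ph in range(5))
    assert np.ptp(total) < 1e-9
    assert np.allclose(total, 5.0, atol=1e-9)


def test_pattern_fourier_peaks(config):
    p = SIMPattern(angle_index=0, modulation_depth=0.9, axial=False)
    plane = sim_pattern(p, config, (1, 256, 256), z_planes_nm=[0.0])[0]
    spec = np.abs(np.fft.fft2(plane - plane.mean()))
    fx = np.fft.fftfreq(256, config.voxel_xy_nm)
    f_pat = 0.8 * config.excitation_coherent_cutoff
    peak = np.unravel_index(spec.argmax(), spec.shape)
    assert peak[0] == 0  # angle 0 modulates along x
    assert abs(abs(fx[peak[1]]) - f_pat) <= 1.0 / (256 * config.voxel_xy_nm)


def test_pattern_above_cutoff_rejected(config):
    with pytest.raises(ValueError):
        sim_pattern(SIMPattern(k_frac=1.2), config, (1, 32, 32))


# --- rendering --------------------------------------------------------------

def test_delta_phantom_returns_psf(config):
    vol = np.zeros((1, 64, 64))
    vol[0, 32, 32] = 1.0
    ph = Phantom("delta", vol, config.voxel_xy_nm, config.voxel_z_nm)
    img = render_widefield(ph, None, config, focal_planes_nm=[0.0])[0]
    from aosim import build_pupil, pupil_to_psf
    psf = pupil_to_psf(build_pupil(config, None, grid_size=128), [0.0],
                       normalization="none").intensity[0]
    psf = psf / psf.max()
    got = img / img.max()
    assert np.allclose(got[16:48, 16:48], psf[48:80, 48:80], atol=1e-9)


def test_rendering_linear_in_phantom(config, bead_scene):
    img1 = render_widefield(bead_scene, None, config, focal_planes_nm=[0.0])
    ph2 = Phantom("scaled", 2.5 * bead_scene.volume, config.voxel_xy_nm,
                  config.voxel_z_nm)
    img2 = render_widefield(ph2, None, config, focal_planes_nm=[0.0])
    assert np.allclose(img2, 2.5 * img1, rtol=1e-10)


def test_aberrated_render_dimmer(config, bead_scene):
    clean = render_widefield(bead_scene, None, config,
                             focal_planes_nm=[0.0]).max()
    ab = render_widefield(bead_scene, ZernikeVector({11: 1.0}), config,
                         focal_planes_nm=[0.0]).max()
    assert ab < clean


def test_photon_budget_scales_signal(config, bead_scene):
    out = []
    for budget in (300.0, 600.0):
        nm = NoiseModel(photon_budget=budget, read_noise_e=0.0,
                        background=0.0, seed=1)
        img = render_widefield(bead_scene, None, config, noise=nm,
                               focal_planes_nm=[0.0],
                               rng=np.random.default_rng(1))
        out.append(img.sum())
    assert out[1] / out[0] == pytest.approx(2.0, rel=0.05)


def test_noise_seeded_reproducibility(config, bead_scene):
    nm = NoiseModel(seed=42)
    a = render_widefield(bead_scene, None, config, noise=nm,
                         focal_planes_nm=[0.0])
    b = render_widefield(bead_scene, None, config, noise=NoiseModel(seed=42),
                         focal_planes_nm=[0.0])
    assert np.array_equal(a, b)


# --- SIM stack --------------------------------------------------------------

def test_stack_frame_count_and_extents(config):
    ph = make_bead_phantom(2, fov=(1, 32, 32), min_separation_nm=1200.0,
                           seed=1, config=config)
    z = (np.arange(7) - 3) * config.voxel_z_nm
    stack = render_sim_stack(ph, None, config, z, n_channels=2)
    assert stack.n_frames == 210
    assert stack.data.shape[:4] == (5, 3, 7, 2)
    assert stack.data.min() >= 0


def test_zero_modulation_frames_identical(config):
    ph = make_bead_phantom(2, fov=(1, 32, 32), min_separation_nm=1200.0,
                           seed=1, config=config)
    from aosim.scope import _all_patterns
    pats = _all_patterns(0.8, True, 0.0)
    stack = render_sim_stack(ph, None, config, [0.0], patterns=pats)
    ref = stack.data[0, 0, 0, 0]
    assert np.allclose(stack.data[:, :, 0, 0], ref, atol=1e-9)


def test_phase_average_matches_widefield_in_expectation(config):
    """Monte-Carlo equality of means: phase/angle-averaged noisy SIM frames
    converge to the noisy widefield mean of the same scene."""
    ph = make_bead_phantom(2, fov=(1, 32, 32), min_separation_nm=1200.0,
                           seed=1, config=config)
    nm = NoiseModel(photon_budget=500.0, background=0.0)
    sim_means, wf_means = [], []
    for s in range(20):
        stack = render_sim_stack(ph, None, config, [0.0],
                                 noise=NoiseModel(500.0, 2.0, 0.0, seed=s),
                                 seed=s)
        sim_means.append(stack.data[:, :, 0, 0].mean())
        wf = render_widefield(ph, None, config,
                              noise=NoiseModel(500.0, 2.0, 0.0, seed=1000 + s),
                              focal_planes_nm=[0.0])
        wf_means.append(wf.mean())
    diff = np.mean(sim_means) - np.mean(wf_means)
    pooled_se = np.sqrt(np.var(sim_means) / 20 + np.var(wf_means) / 20)
    assert abs(diff) < max(4 * pooled_se, 0.01 * np.mean(wf_means))


def test_stack_shape_validation(config):
    with pytest.raises(ValueError):
        RawSIMStack(np.zeros((4, 3, 1, 1, 8, 8)), np.zeros(1), 100.0, 125.0)


def test_scope_render_count_increments(noiseless_scope):
    scope = noiseless_scope()
    scope.render_frame(None)
    scope.render_frame(ZernikeVector({11: 0.3}))
    assert scope.render_count == 2
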