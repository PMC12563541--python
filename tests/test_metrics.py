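import numpy as np
import pytest

from aosim import (OpticalConfig, Phantom, SIMPattern, ZernikeVector,
                   bead_fwhm, build_pupil, detect_beads, make_bead_phantom,
                   modulation_contrast, pseudo_widefield, pupil_to_psf,
                   render_sim_stack, render_widefield, spectral_resolution,
                   NoiseModel)
from aosim.metrics import FWHM_PER_SIGMA
from aosim.scope import RawSIMStack


# --- pseudo-widefield -------------------------------------------------------

def test_pwf_equals_widefield_noiseless(config):
    """Five-phase cancellation: averaging the raw SI frames reproduces the
    widefield image of the same scene exactly (noiseless)."""
    ph = make_bead_phantom(3, fov=(1, 64, 64), min_separation_nm=1500.0,
                           seed=2, config=config)
    stack = render_sim_stack(ph, None, config, [0.0])
    wf = render_widefield(ph, None, config, focal_planes_nm=[0.0])
    pwf = pseudo_widefield(stack)
    assert pwf.shape == (1, 1, 64, 64)
    assert np.abs(pwf[0, 0] - wf[0]).max() < 1e-6 * wf[0].max()


def test_pwf_extents_and_missing_frame_error(config):
    data = np.ones((5, 3, 2, 2, 8, 8))
    stack = RawSIMStack(data, np.array([0.0, 125.0]), 100.0, 125.0)
    assert pseudo_widefield(stack).shape == (2, 2, 8, 8)
    data[2, 1, 0, 1] = np.nan
    with pytest.raises(ValueError) as err:
        pseudo_widefield(stack)
    assert "(2, 1, 0, 1)" in str(err.value)


# --- bead detection ---------------------------------------------------------

def test_single_bead_detection(config):
    ph = make_bead_phantom(1, fov=(1, 64, 64), seed=0, config=config)
    img = render_widefield(ph, None, config, focal_planes_nm=[0.0])[0]
    locs = detect_beads(img)
    assert len(locs) == 1
    assert np.hypot(locs[0][0] - 31.5, locs[0][1] - 31.5) < 1.5


def test_two_separated_beads(config):
    img = np.zeros((64, 64))
    img[16, 16] = img[48, 48] = 1.0
    from scipy.ndimage import gaussian_filter
    img = gaussian_filter(img, 1.5)
    assert len(detect_beads(img, min_separation_vox=3)) == 2


def test_seeded_field_detection_accuracy(config):
    """>= 45 of 50 beads found at default noise; no false positives away
    from any true bead."""
    ph = make_bead_phantom(50, fov=(1, 256, 256), min_separation_nm=1500.0,
                           seed=9, config=config)
    img = render_widefield(ph, None, config, noise=NoiseModel(seed=9),
                           focal_planes_nm=[0.0],
                           rng=np.random.default_rng(9))[0]
    locs = detect_beads(img, min_separation_vox=5, intensity_floor=0.25)
    truth = np.array([(c[1], c[2]) for c in ph.params["centers_vox"]])
    matched = 0
    for t in truth:
        if len(locs) and np.min(np.linalg.norm(locs - t, axis=1)) < 2.0:
            matched += 1
    assert matched >= 45
    for l in locs:
        assert np.min(np.linalg.norm(truth - l, axis=1)) <= 3.0


# --- FWHM -------------------------------------------------------------------

def test_fwhm_identity_on_synthetic_gaussian():
    sigma_nm, vx = 141.6, 100.0
    yy, xx = np.mgrid[0:41, 0:41].astype(float)
    img = np.exp(-(((yy - 20) * vx) ** 2 + ((xx - 20) * vx) ** 2)
                 / (2 * sigma_nm ** 2))
    rep = bead_fwhm(img, [[20.0, 20.0]], vx)
    assert rep.lateral_mean_nm == pytest.approx(FWHM_PER_SIGMA * sigma_nm,
                                                abs=0.5)


@pytest.mark.parametrize("sigma_nm", [100.0, 200.0, 300.0, 400.0])
def test_fwhm_unbiased_across_widths(sigma_nm):
    """The estimator is unbiased (< 0.5% error) on noiseless Gaussians
    across the physically relevant width range."""
    vx = 100.0
    n = 61
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    c = n // 2
    img = 0.1 + np.exp(-(((yy - c) * vx) ** 2 + ((xx - c) * vx) ** 2)
                       / (2 * sigma_nm ** 2))
    rep = bead_fwhm(img, [[float(c), float(c)]], vx, fit_halfwidth_vox=20)
    expected = FWHM_PER_SIGMA * sigma_nm
    assert abs(rep.lateral_mean_nm - expected) / expected < 0.005


def test_rendered_bead_fwhm_matches_oracle(config):
    """Simulated 100 nm bead FWHM within 5% of the quadrature-oracle PSF
    convolved with the bead profile."""
    from _oracles import lateral_fwhm_oracle
    ph = make_bead_phantom(1, fov=(1, 64, 64), seed=0, config=config)
    img = render_widefield(ph, None, config, focal_planes_nm=[0.0])[0]
    rep = bead_fwhm(img, detect_beads(img), config.voxel_xy_nm)
    psf_fwhm = lateral_fwhm_oracle(config)
    # quadrature broadening by the 100 nm projected-disk bead profile
    bead_sigma = 100.0 / 4.0  # RMS width of a uniform disk of diameter d
    expected = np.sqrt(psf_fwhm ** 2 + (FWHM_PER_SIGMA * bead_sigma) ** 2)
    assert rep.lateral_mean_nm == pytest.approx(expected, rel=0.05)


def test_spherical_aberration_broadens_axially(config):
    z = (np.arange(33) - 16) * config.voxel_z_nm
    reports = []
    for a in (0.0, 1.0):
        psf = pupil_to_psf(build_pupil(config, ZernikeVector({11: a}),
                                       grid_size=64), z)
        vol = psf.intensity
        loc = np.array(np.unravel_index(vol.argmax(), vol.shape), float)
        rep = bead_fwhm(vol, [loc], config.voxel_xy_nm, config.voxel_z_nm,
                        r2_min=0.5)
        reports.append(rep.axial_mean_nm)
    assert reports[1] > reports[0]


def test_all_rejected_raises():
    img = np.random.default_rng(0).normal(size=(31, 31))
    with pytest.raises(RuntimeError):
        bead_fwhm(img, [[15.0, 15.0]], 100.0, r2_min=0.999)


# --- spectral resolution ----------------------------------------------------

def test_psf_lateral_cutoff_matches_theory(config):
    z = (np.arange(33) - 16) * config.voxel_z_nm
    psf = pupil_to_psf(build_pupil(config, None, grid_size=128), z)
    rep = spectral_resolution(psf.intensity, config.voxel_xy_nm,
                              config.voxel_z_nm)
    fc = config.emission_cutoff * 1e3  # 1/um
    bin_um = 1e3 / (128 * config.voxel_xy_nm)
    assert abs(rep.lateral_cutoff_um - fc) <= bin_um


def test_hard_band_limit_recovered():
    """A volume band-limited at 2 / um must report 500 nm resolution."""
    rng = np.random.default_rng(0)
    vol = rng.normal(size=(33, 64, 64)) ** 2
    f = np.fft.fftfreq(64, 100.0)
    fz = np.fft.fftfreq(33, 125.0)
    fr = np.hypot(f[:, None], f[None, :])[None]
    mask = (fr <= 2e-3) & (np.abs(fz)[:, None, None] <= 2e-3)
    volf = np.fft.ifftn(np.fft.fftn(vol) * mask).real
    rep = spectral_resolution(volf, 100.0, 125.0, window=False)
    bin_nm = 1.0 / 2.0e-3 - 1.0 / (2.0e-3 + 1.0 / 6400.0)
    assert rep.lateral_resolution_nm == pytest.approx(500.0, abs=bin_nm + 1)


def test_spectral_invariance_to_scale_and_offset(config):
    z = (np.arange(17) - 8) * config.voxel_z_nm
    psf = pupil_to_psf(build_pupil(config, None, grid_size=64), z).intensity
    r0 = spectral_resolution(psf, 100.0, 125.0)
    r1 = spectral_resolution(40.0 * psf + 3.0, 100.0, 125.0)
    assert r1.lateral_cutoff_um == pytest.approx(r0.lateral_cutoff_um,
                                                 rel=0.02)


def test_doubled_support_doubles_cutoff(config):
    """Rendering with doubled OTF support doubles the measured lateral
    cutoff within 15% (the resolution-doubling bookkeeping check)."""
    cfg = OpticalConfig(voxel_xy_nm=50.0)  # Nyquist for the doubled support
    ph = make_bead_phantom(5, fov=(1, 128, 128), min_separation_nm=800.0,
                           seed=5, config=cfg)
    img_wf = render_widefield(ph, None, cfg, focal_planes_nm=[0.0])
    from dataclasses import replace
    cfg2 = replace(cfg, lambda_em_nm=cfg.lambda_em_nm / 2)
    img_2x = render_widefield(ph, None, cfg2, focal_planes_nm=[0.0])
    r_wf = spectral_resolution(img_wf, cfg.voxel_xy_nm, 125.0)
    r_2x = spectral_resolution(img_2x, cfg.voxel_xy_nm, 125.0)
    ratio = r_2x.lateral_cutoff_um / r_wf.lateral_cutoff_um
    assert ratio == pytest.approx(2.0, rel=0.15)


def test_degradation_monotonic_in_spherical(config):
    """Lateral OTF-support resolution never improves as spherical
    aberration grows."""
    z = (np.arange(17) - 8) * config.voxel_z_nm
    cuts = []
    for a in (0.0, 0.5, 1.0, 1.5):
        psf = pupil_to_psf(build_pupil(config, ZernikeVector({11: a}),
                                       grid_size=64), z)
        rep = spectral_resolution(psf.intensity, config.voxel_xy_nm,
                                  config.voxel_z_nm)
        cuts.append(rep.lateral_cutoff_um)
    assert all(b <= a + 0.05 * cuts[0] for a, b in zip(cuts, cuts[1:]))


def test_small_volume_rejected():
    with pytest.raises(ValueError):
        spectral_resolution(np.ones((8, 16, 16)), 100.0, 125.0)


# --- modulation contrast ----------------------------------------------------

def _pattern_stack(config, m, noise_sd=0.0, seed=0):
    from aosim.scope import sim_pattern
    frames = np.zeros((5, 3, 1, 1, 64, 64))
    rng = np.random.default_rng(seed)
    for a in range(3):
        for p in range(5):
            pt = SIMPattern(angle_index=a, phase_index=p, modulation_depth=m)
            f = sim_pattern(pt, config, (1, 64, 64), z_planes_nm=[0.0])[0]
            if noise_sd:
                f = f + rng.normal(0, noise_sd, f.shape)
            frames[p, a, 0, 0] = f
    return RawSIMStack(frames, np.array([0.0]), config.voxel_xy_nm,
                       config.voxel_z_nm)


def test_contrast_equals_modulation_depth(config):
    """Closed-form five-point DFT: a pure pattern of depth m scores m."""
    for m in (0.3, 0.7, 1.0):
        c = modulation_contrast(_pattern_stack(config, m))
        assert np.allclose(c, m, atol=1e-3)


def test_zero_modulation_contrast_below_noise_floor(config):
    c = modulation_contrast(_pattern_stack(config, 0.0, noise_sd=0.01))
    # noise-only first harmonic: mean |X1| scales as sd * sqrt(5 * pi / 4)
    floor = 3 * 0.01
    assert np.all(c < floor)


def test_contrast_decreases_with_photon_budget(config):
    """Lower photon budgets (deeper, more scattering) reduce the measured
    stripe contrast monotonically."""
    ph = make_bead_phantom(5, fov=(1, 64, 64), min_separation_nm=1200.0,
                           seed=3, config=config)
    means = []
    for budget in (2000.0, 200.0, 20.0):
        stack = render_sim_stack(
            ph, None, config, [0.0],
            noise=NoiseModel(budget, 2.0, 5.0, seed=1), seed=1)
        means.append(modulation_contrast(stack).mean())
    assert means[0] > means[1] > means[2]
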