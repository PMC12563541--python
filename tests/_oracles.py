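"""Independent numerical oracles used only by the tests.

These deliberately avoid the FFT code path of the package: the PSF oracle
evaluates the scalar Debye diffraction integral for a circularly symmetric
pupil as a direct Hankel-transform quadrature, so agreement with the FFT
renderer is a genuine two-route check.
"""

import numpy as np
from scipy.special import j0


def debye_psf_radial(radii_nm, z_nm, config, n_quad=600):
    """|E(r, z)|^2 for an unaberrated circular pupil by direct quadrature.

    E(r, z) = int_0^{fmax} J0(2 pi f r) exp(i kz(f) z) 2 pi f df with
    kz(f) = (2 pi n / lambda) sqrt(1 - (lambda f / n)^2): the continuum
    limit of the 2D Fourier transform the package computes discretely.
    """
    f_max = config.na / config.lambda_em_nm
    f = (np.arange(n_quad) + 0.5) / n_quad * f_max
    df = f_max / n_quad
    n_imm = config.n_immersion
    lam = config.lambda_em_nm
    kz = (2 * np.pi * n_imm / lam) * np.sqrt(
        np.clip(1.0 - (lam * f / n_imm) ** 2, 0.0, None))
    radii = np.atleast_1d(np.asarray(radii_nm, dtype=float))
    bessel = j0(2 * np.pi * np.outer(radii, f))        # (n_r, n_quad)
    out = np.empty((len(np.atleast_1d(z_nm)), len(radii)))
    for i, z in enumerate(np.atleast_1d(z_nm)):
        phase = np.exp(1j * kz * z)
        amp = bessel @ (phase * 2 * np.pi * f * df)
        out[i] = np.abs(amp) ** 2
    return out


def debye_psf_volume(shape, config, n_quad=600):
    """Oracle PSF on the same (z, y, x) voxel grid the package renders."""
    nz, ny, nx = shape
    z = (np.arange(nz) - nz // 2) * config.voxel_z_nm
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    r = np.hypot((yy - ny // 2) * config.voxel_xy_nm,
                 (xx - nx // 2) * config.voxel_xy_nm)
    r_unique, inv = np.unique(np.round(r, 6), return_inverse=True)
    prof = debye_psf_radial(r_unique, z, config, n_quad=n_quad)
    return prof[:, inv].reshape(nz, ny, nx)


def lateral_fwhm_oracle(config, n_quad=2000):
    """Lateral FWHM (nm) of the in-focus oracle PSF by bisection."""
    peak = debye_psf_radial([0.0], [0.0], config, n_quad)[0, 0]

    def half(r):
        return debye_psf_radial([r], [0.0], config, n_quad)[0, 0] - peak / 2

    lo, hi = 0.0, config.lambda_em_nm / config.na
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if half(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 2.0 * 0.5 * (lo + hi)
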