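"""Zernike polynomials in the Noll single-index convention.

Modes are RMS-normalized over the unit disk (Noll normalization), so a
coefficient of ``a`` radians on any single mode contributes exactly ``a``
radians of RMS wavefront error.  Piston (j = 1) carries no image information
and is excluded from :class:`ZernikeVector`.

Noll ordering within a radial order ``n``: |m| ascending, with even ``j``
assigned the cosine (m > 0) term and odd ``j`` the sine (m < 0) term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "noll_to_nm",
    "nm_to_noll",
    "noll_label",
    "zernike_eval",
    "ZernikeVector",
]

# Common-usage names for the low-order modes the correction loop handles.
_LABELS = {
    2: "tip",
    3: "tilt",
    4: "defocus",
    5: "primary oblique astigmatism",
    6: "primary vertical astigmatism",
    7: "vertical coma",
    8: "horizontal coma",
    9: "oblique trefoil",
    10: "vertical trefoil",
    11: "primary spherical",
    12: "secondary vertical astigmatism",
    13: "secondary oblique astigmatism",
    22: "secondary spherical",
    37: "tertiary spherical",
}

_NOLL_CACHE: Dict[int, Tuple[int, int]] = {}
_NM_CACHE: Dict[Tuple[int, int], int] = {}


def _extend_noll_table(j_max: int) -> None:
    if j_max <= len(_NOLL_CACHE):
        return
    _NOLL_CACHE.clear()
    _NM_CACHE.clear()
    j, n = 1, 0
    while j <= j_max:
        for am in range(n % 2, n + 1, 2):  # |m| ascending within order n
            if am == 0:
                _NOLL_CACHE[j] = (n, 0)
                j += 1
            else:
                # even index -> cosine (+m), odd index -> sine (-m)
                for jj in (j, j + 1):
                    _NOLL_CACHE[jj] = (n, am if jj % 2 == 0 else -am)
                j += 2
        n += 1
    for jj, nm in _NOLL_CACHE.items():
        _NM_CACHE[nm] = jj


def noll_to_nm(j: int) -> Tuple[int, int]:
    """Map a Noll index to (radial order n, signed azimuthal order m).

    Raises ``ValueError`` for non-integer or ``j < 1`` input.
    """
    if isinstance(j, bool) or not isinstance(j, (int, np.integer)):
        raise ValueError(f"Noll index must be an integer, got {j!r}")
    j = int(j)
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    if j not in _NOLL_CACHE:
        _extend_noll_table(max(j, 66))
    return _NOLL_CACHE[j]


def nm_to_noll(n: int, m: int) -> int:
    """Inverse of :func:`noll_to_nm`."""
    if n < 0 or abs(m) > n or (n - abs(m)) % 2 != 0:
        raise ValueError(f"invalid Zernike orders (n={n}, m={m})")
    j_max = (n + 1) * (n + 2) // 2
    _extend_noll_table(max(j_max, 66))
    return _NM_CACHE[(n, m)]


def noll_label(j: int) -> str:
    """Human-readable name of mode ``j`` (falls back to ``Z<j> (n, m)``)."""
    n, m = noll_to_nm(j)
    return _LABELS.get(int(j), f"Z{j} (n={n}, m={m})")


def _radial_poly(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m_abs) // 2 + 1):
        c = ((-1) ** k * math.factorial(n - k)
             / (math.factorial(k)
                * math.factorial((n + m_abs) // 2 - k)
                * math.factorial((n - m_abs) // 2 - k)))
        out += c * rho ** (n - 2 * k)
    return out


def zernike_eval(j: int, rho, theta, outside: str = "raise"):
    """Evaluate RMS-normalized Zernike mode ``j`` at polar coordinates.

    Parameters
    ----------
    rho, theta : array-like
        Normalized pupil radius (0 <= rho <= 1) and azimuth in radians.
    outside : {"raise", "zero"}
        Behaviour for rho > 1: raise a domain error, or return 0 there
        (useful when evaluating on a square grid with a circular mask).
    """
    rho = np.asarray(rho, dtype=float)
    theta = np.asarray(theta, dtype=float)
    bad = rho > 1.0 + 1e-12
    if np.any(bad):
        if outside == "raise":
            raise ValueError("rho > 1 outside the unit pupil")
        rho = np.where(bad, 0.0, rho)
    n, m = noll_to_nm(j)
    r = _radial_poly(n, abs(m), rho)
    if m == 0:
        val = math.sqrt(n + 1) * r
    elif m > 0:
        val = math.sqrt(2 * (n + 1)) * r * np.cos(m * theta)
    else:
        val = math.sqrt(2 * (n + 1)) * r * np.sin(-m * theta)
    if np.any(bad):
        val = np.where(bad, 0.0, val)
    return val


@dataclass
class ZernikeVector:
    """Noll-indexed wavefront coefficients in phase radians.

    ``reference_wavelength_nm`` pins the physical meaning of "radians":
    one radian of phase corresponds to ``lambda / (2 pi)`` nanometres of
    wavefront at that wavelength.

    Supports index-wise ``+``, ``-``, unary ``-`` and scalar ``*``.
    """

    coefficients: Dict[int, float] = field(default_factory=dict)
    reference_wavelength_nm: float = 525.0
    meta: Optional[dict] = None

    def __post_init__(self) -> None:
        clean: Dict[int, float] = {}
        for j, a in dict(self.coefficients).items():
            ji = int(j)
            if ji != j or ji < 2:
                raise ValueError(
                    f"mode index must be an integer >= 2 (piston excluded), got {j!r}"
                )
            a = float(a)
            if not math.isfinite(a):
                raise ValueError(f"non-finite amplitude for mode {ji}: {a}")
            clean[ji] = a
        self.coefficients = clean

    # --- container protocol -------------------------------------------------
    def __getitem__(self, j: int) -> float:
        return self.coefficients.get(int(j), 0.0)

    def __contains__(self, j: int) -> bool:
        return int(j) in self.coefficients

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self.coefficients))

    def __len__(self) -> int:
        return len(self.coefficients)

    @property
    def modes(self) -> Tuple[int, ...]:
        return tuple(sorted(self.coefficients))

    # --- algebra ------------------------------------------------------------
    def _check_wavelength(self, other: "ZernikeVector") -> None:
        if not math.isclose(self.reference_wavelength_nm,
                            other.reference_wavelength_nm,
                            rel_tol=1e-9):
            raise ValueError(
                "cannot combine ZernikeVectors with different reference "
                f"wavelengths ({self.reference_wavelength_nm} vs "
                f"{other.reference_wavelength_nm} nm)"
            )

    def __add__(self, other: "ZernikeVector") -> "ZernikeVector":
        self._check_wavelength(other)
        modes = set(self.coefficients) | set(other.coefficients)
        return ZernikeVector(
            {j: self[j] + other[j] for j in modes},
            reference_wavelength_nm=self.reference_wavelength_nm,
        )

    def __sub__(self, other: "ZernikeVector") -> "ZernikeVector":
        return self + (-other)

    def __neg__(self) -> "ZernikeVector":
        return ZernikeVector(
            {j: -a for j, a in self.coefficients.items()},
            reference_wavelength_nm=self.reference_wavelength_nm,
        )

    def __mul__(self, s: float) -> "ZernikeVector":
        return ZernikeVector(
            {j: s * a for j, a in self.coefficients.items()},
            reference_wavelength_nm=self.reference_wavelength_nm,
        )

    __rmul__ = __mul__

    def with_mode(self, j: int, amplitude_rad: float) -> "ZernikeVector":
        coeffs = dict(self.coefficients)
        coeffs[int(j)] = float(amplitude_rad)
        return ZernikeVector(coeffs, self.reference_wavelength_nm)

    def rms(self) -> float:
        """RMS wavefront error in radians (modes are orthonormal)."""
        return math.sqrt(sum(a * a for a in self.coefficients.values()))

    # --- unit conversion ----------------------------------------------------
    def to_nm(self) -> Dict[int, float]:
        """Coefficients as nanometres of wavefront at the reference wavelength."""
        s = self.reference_wavelength_nm / (2.0 * math.pi)
        return {j: a * s for j, a in self.coefficients.items()}

    @classmethod
    def from_nm(cls, coeffs_nm: Mapping[int, float],
                reference_wavelength_nm: float = 525.0) -> "ZernikeVector":
        s = 2.0 * math.pi / reference_wavelength_nm
        return cls({j: a * s for j, a in coeffs_nm.items()},
                   reference_wavelength_nm)

    def as_dict(self) -> Dict[int, float]:
        return dict(self.coefficients)
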