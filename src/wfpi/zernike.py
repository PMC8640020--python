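"""OSA-standard Zernike machinery for ocular wavefront analysis.

Implements the single-index OSA/ANSI Zernike basis (j = [n(n+2)+m]/2, unit
mean-square normalisation over the unit disk), least-squares fitting of phase
maps over a circular pupil, aberration band statistics, conversion of the
second-order coefficients to a sphero-cylindrical refraction, and the pupil
geometry helpers (largest inscribed circle, bilinear resampling) used when
comparing against lenslet-array sensors.

Conventions
-----------
* Coefficients are in micrometres of optical path over the fitting circle.
* The pupil coordinate frame has x along columns (increasing right) and y
  increasing *upwards*, i.e. ``y = (center_row - row) / radius``, so that the
  astigmatic axis follows the ophthalmic counter-clockwise-from-horizontal
  convention.
* Refraction is reported in the minus-cylinder convention.  The spherical
  value is the spherical equivalent M without the usual C/2 transposition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import PhaseMap

N_TERMS_DEFAULT = 66

#: OSA band boundaries (single-index j, inclusive).
BANDS = {
    "low": (3, 5),
    "medium": (6, 14),
    "high": (15, 65),
    "total": (3, 65),
}


def osa_to_nm(j: int) -> tuple[int, int]:
    """Convert the OSA single index j to (radial order n, azimuthal frequency m)."""
    if j < 0:
        raise ValueError(f"OSA index must be non-negative, got {j}")
    n = int((math.isqrt(8 * j + 1) - 1) // 2)
    m = 2 * j - n * (n + 2)
    return n, m


def nm_to_osa(n: int, m: int) -> int:
    return (n * (n + 2) + m) // 2


def _radial_poly(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    out = np.zeros_like(rho)
    for s in range((n - m_abs) // 2 + 1):
        c = ((-1) ** s * math.factorial(n - s)
             / (math.factorial(s)
                * math.factorial((n + m_abs) // 2 - s)
                * math.factorial((n - m_abs) // 2 - s)))
        out += c * rho ** (n - 2 * s)
    return out


def zernike_values(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Evaluate the orthonormal OSA Zernike polynomial Z_j at polar points.

    Normalised so that the mean-square value over the unit disk is 1.
    """
    n, m = osa_to_nm(j)
    norm = math.sqrt(2 * (n + 1) / (1 + (1 if m == 0 else 0)))
    rad = _radial_poly(n, abs(m), rho)
    if m > 0:
        ang = np.cos(m * theta)
    elif m < 0:
        ang = np.sin(-m * theta)
    else:
        ang = np.ones_like(theta)
    return norm * rad * ang


@dataclass
class ZernikeCoeffs:
    """OSA-indexed Zernike coefficient vector tied to a pupil circle.

    Attributes
    ----------
    coeffs : (n_terms,) array, micrometres.
    pupil_center : (row, col) pixel coordinates of the fitting circle centre.
    pupil_radius_px : circle radius in pixels.
    pixel_pitch : metres per pixel in the pupil plane.
    """

    coeffs: np.ndarray
    pupil_center: tuple[float, float]
    pupil_radius_px: float
    pixel_pitch: float
    fit_rms_residual: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("Zernike coefficients must be finite")
        if self.pupil_radius_px <= 0:
            raise ValueError("pupil radius must be positive")

    @property
    def pupil_radius_m(self) -> float:
        return self.pupil_radius_px * self.pixel_pitch

    def __getitem__(self, j: int) -> float:
        return float(self.coeffs[j])

    def to_json(self) -> str:
        rows = []
        for j, c in enumerate(self.coeffs):
            n, m = osa_to_nm(j)
            rows.append({"j": j, "n": n, "m": m, "value_um": float(c)})
        return json.dumps({
            "pupil_center": list(self.pupil_center),
            "pupil_radius_px": self.pupil_radius_px,
            "pixel_pitch_m": self.pixel_pitch,
            "coefficients": rows,
        }, indent=1)


@dataclass
class SpheroCylinder:
    """Sphero-cylindrical refraction in the minus-cylinder convention.

    M is the spherical equivalent reported directly as the "sphere" value
    (no C/2 transposition).  Units: diopters and degrees, axis in [0, 180).
    """

    M: float
    J0: float
    J45: float
    cylinder: float
    axis: float

    def __post_init__(self) -> None:
        if self.cylinder > 1e-12:
            raise ValueError("minus-cylinder convention: cylinder must be <= 0")
        if not (0.0 <= self.axis < 180.0):
            raise ValueError(f"axis must lie in [0, 180), got {self.axis}")

    def as_plus_cylinder(self) -> tuple[float, float]:
        """Return (cylinder power, axis) transposed to the plus-cylinder form."""
        return -self.cylinder, (self.axis + 90.0) % 180.0

    def to_dict(self) -> dict:
        return {"M": self.M, "J0": self.J0, "J45": self.J45,
                "cylinder": self.cylinder, "axis": self.axis}


def _unit_disk_coords(shape: tuple[int, int], center: tuple[float, float],
                      radius: float) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = np.indices(shape, dtype=float)
    x = (cols - center[1]) / radius
    y = (center[0] - rows) / radius  # y up
    return x, y


def zernike_surface(j: int, shape: tuple[int, int], center: tuple[float, float],
                    radius: float, pixel_pitch: float = 1.0) -> PhaseMap:
    """Sample the orthonormal Zernike polynomial Z_j on a pixel grid.

    The unit disk is mapped to the circle (center, radius) in pixel
    coordinates; values outside the disk are masked out.
    """
    if not 0 <= j < N_TERMS_DEFAULT:
        raise ValueError(f"OSA index out of supported range [0, 65]: {j}")
    x, y = _unit_disk_coords(shape, center, radius)
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    mask = rho <= 1.0
    vals = np.where(mask, zernike_values(j, rho, theta), 0.0)
    return PhaseMap(values=vals, mask=mask, pixel_pitch=pixel_pitch)


def phase_from_coeffs(coeffs: np.ndarray, shape: tuple[int, int],
                      center: tuple[float, float], radius: float,
                      pixel_pitch: float = 1.0) -> PhaseMap:
    """Synthesise a phase map (µm) from OSA coefficients on a pupil circle."""
    x, y = _unit_disk_coords(shape, center, radius)
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    mask = rho <= 1.0
    vals = np.zeros(shape, dtype=float)
    for j, c in enumerate(np.asarray(coeffs, dtype=float)):
        if c != 0.0:
            vals[mask] += c * zernike_values(j, rho[mask], theta[mask])
    return PhaseMap(values=vals, mask=mask, pixel_pitch=pixel_pitch)


def fit_zernike(phase: PhaseMap, center: tuple[float, float], radius: float,
                n_terms: int = N_TERMS_DEFAULT) -> ZernikeCoeffs:
    """Least-squares OSA Zernike coefficients of a phase map over a circle.

    Ordinary least squares on the pixel samples inside the circle (no
    quadrature weighting), the common choice in aberrometry where pupils are
    pixel-limited.  Raises if the circle holds too few valid pixels for a
    well-conditioned fit.
    """
    x, y = _unit_disk_coords(phase.values.shape, center, radius)
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    sel = (rho <= 1.0) & phase.mask
    npx = int(sel.sum())
    if npx < 4 * n_terms:
        raise ValueError(
            f"only {npx} pixels inside the fitting circle; too few for "
            f"{n_terms} Zernike terms")
    design = np.empty((npx, n_terms))
    r, t = rho[sel], theta[sel]
    for j in range(n_terms):
        design[:, j] = zernike_values(j, r, t)
    target = phase.values[sel]
    sol, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < n_terms:
        raise ValueError("ill-conditioned Zernike design matrix "
                         "(circle too small for the requested terms)")
    resid = target - design @ sol
    return ZernikeCoeffs(
        coeffs=sol, pupil_center=center, pupil_radius_px=radius,
        pixel_pitch=phase.pixel_pitch,
        fit_rms_residual=float(np.sqrt(np.mean(resid ** 2))),
    )


def band_rms(c: ZernikeCoeffs, band: str) -> float:
    """RMS wavefront error (µm) of an aberration band.

    Bands follow the OSA single index: low = j 3-5, medium = j 6-14,
    high = j 15-65; total excludes piston and tip/tilt (j 0-2).
    """
    try:
        lo, hi = BANDS[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    sel = c.coeffs[lo:hi + 1]
    return float(np.sqrt(np.sum(sel ** 2)))


def to_sphero_cylinder(c: ZernikeCoeffs) -> SpheroCylinder:
    """Sphero-cylindrical refraction from the second-order coefficients.

    M = −4√3 c4 / r², J0 = −2√6 c5 / r², J45 = −2√6 c3 / r² with the
    coefficients in metres and the pupil radius r in metres, yielding
    diopters.  The cylinder is reported in the minus convention and M is
    reported as the sphere value without adding half the cylinder.
    """
    r = c.pupil_radius_m
    if r <= 0:
        raise ValueError("pupil radius must be positive")
    c3, c4, c5 = (c.coeffs[3] * 1e-6, c.coeffs[4] * 1e-6, c.coeffs[5] * 1e-6)
    M = -4.0 * math.sqrt(3.0) * c4 / r ** 2
    J0 = -2.0 * math.sqrt(6.0) * c5 / r ** 2
    J45 = -2.0 * math.sqrt(6.0) * c3 / r ** 2
    cyl = -2.0 * math.hypot(J0, J45)
    if cyl == 0.0:
        axis = 0.0
    else:
        axis = math.degrees(0.5 * math.atan2(J45, J0)) % 180.0
    return SpheroCylinder(M=M, J0=J0, J45=J45, cylinder=cyl, axis=axis)


def largest_inscribed_circle(mask: np.ndarray) -> tuple[tuple[int, int], float]:
    """Centre and radius (pixels) of the largest circle inside a binary mask.

    The centre is the interior point maximising the Euclidean distance to the
    mask complement (ties broken by first occurrence in row-major order); the
    radius is that distance less half a pixel so the circle is inscribed.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no inscribed circle")
    padded = np.pad(mask, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    idx = np.unravel_index(int(np.argmax(dist)), dist.shape)
    radius = float(dist[idx]) - 0.5
    return (int(idx[0]), int(idx[1])), max(radius, 0.5)


def resample_phase(phase: PhaseMap, target_shape: tuple[int, int]) -> PhaseMap:
    """Bilinear resampling of a phase map to a new grid shape.

    Corner-aligned bilinear interpolation (exact for affine maps); the mask is
    propagated conservatively — an output pixel is valid only if every input
    pixel contributing to it is valid.
    """
    tr, tc = target_shape
    if tr < 2 or tc < 2:
        raise ValueError(f"degenerate target shape {target_shape}")
    sr, sc = phase.values.shape
    rows = np.linspace(0.0, sr - 1.0, tr)
    cols = np.linspace(0.0, sc - 1.0, tc)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])
    filled = np.where(phase.mask, phase.values, 0.0)
    vals = ndimage.map_coordinates(filled, coords, order=1, mode="nearest")
    mvals = ndimage.map_coordinates(phase.mask.astype(float), coords, order=1,
                                    mode="constant", cval=0.0)
    mask = mvals.reshape(tr, tc) > 1.0 - 1e-9
    scale = (sr - 1.0) / max(tr - 1.0, 1.0)
    return PhaseMap(values=vals.reshape(tr, tc), mask=mask,
                    pixel_pitch=phase.pixel_pitch * scale)
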