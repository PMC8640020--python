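"""Forward model and fixture generator for the two-plane phase sensor.

Builds ground-truth phase maps — pure defocus, trial cylinders, random
66-term Zernike surfaces of the kind a deformable mirror produces, and
band-limited peak-and-valley textures — and propagates them geometrically to
the two intensity planes at ±Δz, so every reconstruction stage can be tested
without hardware.

The propagation model is geometric ray transport: each illuminated pixel is
treated as a ray bundle displaced laterally by ∓Δz·∇W between the pupil
plane and the two acquisition planes, and deposited by bilinear splatting.
This matches the geometrical-optics scaling s²/(2Δz) used by the
reconstruction; wave-optical propagation is out of scope.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import zernike
from .integrate import differentiate
from .types import IntensityImage, PhaseMap, ScaleParams

#: pupil-plane pixel pitch of the reference instrument: 9 µm sensor pixels
#: behind a magnification of 1.0523
SENSOR_PIXEL = 9e-6
MAGNIFICATION = 1.0523
PLANE_SEPARATION = 13.33e-3  # 2Δz


def pupil_pixel_pitch(sensor_pixel: float = SENSOR_PIXEL,
                      magnification: float = MAGNIFICATION) -> float:
    """Pupil-plane sampling pitch: sensor pixel size over magnification."""
    if sensor_pixel <= 0 or magnification <= 0:
        raise ValueError("pixel size and magnification must be positive")
    return sensor_pixel / magnification


@dataclass
class SimulationConfig:
    """Geometry and noise settings of one simulated acquisition.

    Defaults mirror the reference bench: planes separated by 13.33 mm and a
    7 mm artificial pupil.  The grid is desk-scaled: with ``pixel_pitch``
    unset it is chosen so the pupil fills ~87 % of the grid, rather than the
    instrument's native 8.553 µm sampling which would need a ≥ 1024² grid.
    """

    grid_size: int = 256
    pupil_diameter: float = 7e-3
    delta_z: float = PLANE_SEPARATION / 2.0
    pixel_pitch: float | None = None
    edge_px: float = 2.0           # raised-cosine illumination rolloff
    photon_scale: float = 0.0      # 0 = noise free
    read_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_pitch is None:
            self.pixel_pitch = self.pupil_diameter * 1.15 / self.grid_size
        if self.delta_z <= 0:
            raise ValueError("delta_z must be positive")
        if self.pupil_radius_px * 2 >= self.grid_size:
            raise ValueError("pupil does not fit in the grid")

    @property
    def pupil_radius_px(self) -> float:
        return 0.5 * self.pupil_diameter / self.pixel_pitch

    @property
    def center(self) -> tuple[float, float]:
        return ((self.grid_size - 1) / 2.0, (self.grid_size - 1) / 2.0)

    @property
    def scale_params(self) -> ScaleParams:
        return ScaleParams(s=self.pixel_pitch, delta_z=self.delta_z)

    def pupil_mask(self) -> np.ndarray:
        rr, cc = np.indices((self.grid_size, self.grid_size), dtype=float)
        cy, cx = self.center
        return np.hypot(rr - cy, cc - cx) <= self.pupil_radius_px

    def manifest(self) -> dict:
        return dataclasses.asdict(self)

    def manifest_json(self) -> str:
        return json.dumps(self.manifest(), indent=1)


# ----------------------------------------------------------------------
# ground-truth phases
# ----------------------------------------------------------------------

def phase_from_refraction(S: float, C: float, axis_deg: float,
                          config: SimulationConfig) -> PhaseMap:
    """Second-order phase map of a sphero-cylindrical refraction.

    ``S`` is the sphere and ``C`` the (plus- or minus-signed) cylinder at
    ``axis_deg``, in diopters/degrees at the pupil plane.  Constructed in
    closed form from the power-vector components M = S + C/2,
    J0 = −(C/2)cos 2θ, J45 = −(C/2)sin 2θ so that converting the fitted
    Zernike coefficients back to refraction recovers exactly this lens.
    """
    coeffs = _refraction_coeffs(S, C, axis_deg, 0.5 * config.pupil_diameter)
    return zernike.phase_from_coeffs(coeffs, (config.grid_size,) * 2,
                                     config.center, config.pupil_radius_px,
                                     config.pixel_pitch)


def _refraction_coeffs(S: float, C: float, axis_deg: float, radius_m: float
                       ) -> np.ndarray:
    theta = math.radians(axis_deg)
    M = S + 0.5 * C
    J0 = -0.5 * C * math.cos(2 * theta)
    J45 = -0.5 * C * math.sin(2 * theta)
    r2 = radius_m ** 2
    coeffs = np.zeros(zernike.N_TERMS_DEFAULT)
    coeffs[4] = -M * r2 / (4.0 * math.sqrt(3.0)) * 1e6   # metres -> µm
    coeffs[5] = -J0 * r2 / (2.0 * math.sqrt(6.0)) * 1e6
    coeffs[3] = -J45 * r2 / (2.0 * math.sqrt(6.0)) * 1e6
    return coeffs


def random_dm_phase(amplitude_pv: float, seed: int,
                    config: SimulationConfig) -> PhaseMap:
    """Random 66-term Zernike surface rescaled to an exact P–V amplitude (µm).

    Mimics a deformable-mirror command map: i.i.d. standard-normal
    coefficients on modes j = 3…65 (piston and tip/tilt excluded), then the
    whole surface is rescaled so its peak-to-valley equals ``amplitude_pv``.
    Deterministic per seed.
    """
    if amplitude_pv <= 0:
        raise ValueError("amplitude must be positive")
    rng = np.random.default_rng(seed)
    coeffs = np.zeros(zernike.N_TERMS_DEFAULT)
    coeffs[3:] = rng.standard_normal(zernike.N_TERMS_DEFAULT - 3)
    phase = zernike.phase_from_coeffs(coeffs, (config.grid_size,) * 2,
                                      config.center, config.pupil_radius_px,
                                      config.pixel_pitch)
    pv = phase.pv()
    scale = amplitude_pv / pv
    phase.values *= scale
    phase.true_coeffs = coeffs * scale
    return phase


def pattern_phase(amplitude_nm: tuple[float, float], correlation_length: float,
                  seed: int, config: SimulationConfig) -> PhaseMap:
    """Band-limited random peak-and-valley texture (µm) over the pupil.

    White noise band-pass filtered by a difference of Gaussians (σ and 2σ
    with σ = correlation_length / 2 in pixels), giving an oscillatory field
    of in-phase peaks and valleys at the requested spatial scale — a
    low-pass field would mostly be absorbed by a Zernike fit, a texture is
    not.  Rescaled so its P–V falls inside ``amplitude_nm`` (nanometres,
    drawn uniformly in the range).
    """
    lo, hi = amplitude_nm
    if lo < 0 or hi > 1000 or lo > hi:
        raise ValueError("amplitude range must lie within [0, 1000] nm")
    mask = config.pupil_mask()
    if hi == 0:
        return PhaseMap(np.zeros(mask.shape), mask, config.pixel_pitch)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(mask.shape)
    sigma_px = max(0.5 * correlation_length / config.pixel_pitch, 0.5)
    field = (ndimage.gaussian_filter(noise, sigma_px, mode="reflect")
             - ndimage.gaussian_filter(noise, 2.0 * sigma_px, mode="reflect"))
    field -= field[mask].mean()
    target_pv = rng.uniform(lo, hi) * 1e-3  # nm -> µm
    pv = field[mask].max() - field[mask].min()
    field *= target_pv / pv
    field[~mask] = 0.0
    return PhaseMap(field, mask, config.pixel_pitch)


# ----------------------------------------------------------------------
# propagation
# ----------------------------------------------------------------------

def make_illumination(config: SimulationConfig) -> IntensityImage:
    """Uniform pupil disk with a raised-cosine rim to avoid edge aliasing."""
    rr, cc = np.indices((config.grid_size, config.grid_size), dtype=float)
    cy, cx = config.center
    r = np.hypot(rr - cy, cc - cx)
    R = config.pupil_radius_px
    e = config.edge_px
    vals = np.clip((R - r) / e, 0.0, 1.0)
    vals = 0.5 * (1.0 - np.cos(np.pi * vals))
    return IntensityImage(values=vals, pixel_size=config.pixel_pitch)


def propagate(phase: PhaseMap, illumination: IntensityImage,
              p: ScaleParams) -> tuple[IntensityImage, IntensityImage]:
    """Geometric two-plane propagation of an illuminated wavefront.

    Each illuminated pixel is displaced by ∓(Δz/s²)·∇W pixels (∇W taken as
    the discrete phase gradient in metres per pixel step) and deposited by
    bilinear splatting, giving I1 at −Δz and I2 at +Δz.  Total flux is
    conserved exactly; rays that would leave the grid raise an error
    advising a smaller Δz.
    """
    g = differentiate(phase)
    factor = p.delta_z / p.s ** 2
    disp_c = factor * g.grad_h
    disp_r = factor * g.grad_v
    nrows, ncols = phase.values.shape
    flux = illumination.values
    active = flux > 0
    if np.any(active & ~g.mask):
        raise ValueError("illumination extends beyond the phase support")

    def _one_plane(sign: float) -> IntensityImage:
        r0, c0 = np.nonzero(active)
        f = flux[active]
        rr = r0 + sign * disp_r[active]
        cc = c0 + sign * disp_c[active]
        if rr.min() < 0 or rr.max() > nrows - 1 or cc.min() < 0 or cc.max() > ncols - 1:
            raise ValueError(
                "ray displacement exceeds the grid; the phase is too steep "
                "for this delta_z — reduce delta_z or enlarge the grid")
        ri = np.floor(rr).astype(np.int64)
        ci = np.floor(cc).astype(np.int64)
        fr = rr - ri
        fc = cc - ci
        out = np.zeros(nrows * ncols)
        for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc),
                          (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
            idx = np.minimum(ri + dr, nrows - 1) * ncols + np.minimum(ci + dc, ncols - 1)
            out += np.bincount(idx, weights=f * w, minlength=out.size)
        return IntensityImage(values=out.reshape(nrows, ncols),
                              pixel_size=p.s, plane_offset=sign * p.delta_z)

    i1 = _one_plane(-1.0)
    i2 = _one_plane(+1.0)
    return i1, i2


def add_noise(image: IntensityImage, photon_scale: float, read_sigma: float,
              seed: int) -> IntensityImage:
    """Photon (Poisson) plus additive Gaussian read noise, seeded.

    ``photon_scale`` is the number of detected photons per unit of image
    intensity; 0 disables photon noise.  Negative excursions from read noise
    are clipped at zero as a detector would after bias subtraction.
    """
    if photon_scale < 0:
        raise ValueError("photon_scale must be non-negative")
    rng = np.random.default_rng(seed)
    vals = image.values
    if photon_scale > 0:
        vals = rng.poisson(vals * photon_scale).astype(float) / photon_scale
    if read_sigma > 0:
        vals = vals + rng.normal(0.0, read_sigma, size=vals.shape)
    return IntensityImage(values=np.clip(vals, 0.0, None),
                          pixel_size=image.pixel_size,
                          plane_offset=image.plane_offset)


def simulate_pair(phase: PhaseMap, config: SimulationConfig,
                  seed: int | None = None
                  ) -> tuple[IntensityImage, IntensityImage]:
    """Propagate a ground-truth phase through the configured bench."""
    illum = make_illumination(config)
    i1, i2 = propagate(phase, illum, config.scale_params)
    if config.photon_scale > 0 or config.read_sigma > 0:
        s = config.seed if seed is None else seed
        i1 = add_noise(i1, config.photon_scale, config.read_sigma, s)
        i2 = add_noise(i2, config.photon_scale, config.read_sigma, s + 1)
    return i1, i2
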