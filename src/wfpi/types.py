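"""Core data containers shared across the package.

All grids are row-major with the origin at the top-left pixel; x is the
column index, y the row index, pixel centres at integer coordinates
(0-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class IntensityImage:
    """A non-negative 2-D intensity grid with acquisition geometry.

    Parameters
    ----------
    values : 2-D array of non-negative flux (arbitrary units).
    pixel_size : sensor pixel pitch s in metres.
    plane_offset : signed axial offset from the conjugated pupil plane
        (metres); the acquisition convention is I1 at −Δz, I2 at +Δz.
    """

    values: np.ndarray
    pixel_size: float = 1.0
    plane_offset: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 2:
            raise ValueError("intensity image must be a 2-D grid of at least 2x2")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity image contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("intensity image contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def total_flux(self) -> float:
        return float(self.values.sum())


@dataclass
class AngleGrid:
    """k discrete line angles uniformly covering (−π/2, π/2]."""

    k: int
    angles: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 angles")
        # step π/k, last angle exactly π/2
        self.angles = -np.pi / 2 + np.pi / self.k * np.arange(1, self.k + 1)


@dataclass
class LineProfile:
    """Cumulative flux profile along one sampling line.

    ``samples`` is the running sum of bilinearly interpolated image values at
    unit steps of the line's major axis, hence non-decreasing; ``positions``
    are the (row, col) pixel coordinates of the samples.
    """

    line_id: tuple[int, int]
    samples: np.ndarray
    positions: np.ndarray  # (n, 2) row/col

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(np.diff(self.samples) < -1e-9 * max(self.samples[-1], 1.0)):
            raise ValueError("cumulative line profile must be non-decreasing")

    @property
    def total(self) -> float:
        return float(self.samples[-1])


@dataclass
class ScaleParams:
    """Geometric scaling of the two-plane acquisition.

    s: sensor pixel size (m); delta_z: half-separation Δz between each image
    plane and the conjugated pupil plane (m); magnification: instrument
    magnification from pupil to sensor (pupil-plane pixel pitch = s / mag).
    """

    s: float
    delta_z: float
    magnification: float = 1.0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("pixel size must be positive")
        if self.delta_z <= 0:
            raise ValueError("delta_z must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")

    @property
    def pupil_pixel_pitch(self) -> float:
        return self.s / self.magnification


@dataclass
class GradientField:
    """Per-pixel horizontal/vertical phase gradients with validity mask.

    Units are pixels of lateral displacement between the two planes
    (``units="pixels"``) or metres of optical path per pixel step after
    scaling by s²/(2Δz) (``units="metres"``).
    """

    grad_h: np.ndarray
    grad_v: np.ndarray
    mask: np.ndarray
    units: str = "pixels"
    weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.grad_h = np.asarray(self.grad_h, dtype=float)
        self.grad_v = np.asarray(self.grad_v, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.grad_h.shape != self.grad_v.shape or self.grad_h.shape != self.mask.shape:
            raise ValueError("gradient components and mask must share a shape")
        if self.units not in ("pixels", "metres"):
            raise ValueError("units must be 'pixels' or 'metres'")
        for g in (self.grad_h, self.grad_v):
            if not np.all(np.isfinite(g[self.mask])):
                raise ValueError("gradients must be finite inside the mask")


@dataclass
class PhaseMap:
    """Integrated wavefront in micrometres of optical path on a pixel grid."""

    values: np.ndarray
    mask: np.ndarray
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("phase values and mask must share a shape")
        if self.mask.any() and not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("phase must be finite inside the mask")

    # -- statistics over the pupil -------------------------------------
    def rms(self) -> float:
        v = self.values[self.mask]
        return float(np.sqrt(np.mean(v ** 2)))

    def pv(self) -> float:
        v = self.values[self.mask]
        return float(v.max() - v.min())

    def copy(self) -> "PhaseMap":
        return PhaseMap(self.values.copy(), self.mask.copy(), self.pixel_pitch)

    def remove_piston(self) -> "PhaseMap":
        out = self.copy()
        out.values[out.mask] -= out.values[out.mask].mean()
        return out

    def remove_piston_tilt(self) -> "PhaseMap":
        """Subtract the least-squares plane (piston + tip/tilt) over the mask."""
        rows, cols = np.nonzero(self.mask)
        a = np.column_stack([np.ones(rows.size), cols - cols.mean(),
                             rows - rows.mean()])
        coef, *_ = np.linalg.lstsq(a, self.values[self.mask], rcond=None)
        out = self.copy()
        out.values[self.mask] -= a @ coef
        return out

    def masked(self, fill: float = np.nan) -> np.ndarray:
        return np.where(self.mask, self.values, fill)
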