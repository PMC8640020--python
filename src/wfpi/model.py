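"""Model/Results interface to the two-plane wavefront sensor.

`WavefrontModel` holds the observed data (the intensity pair) together with
the acquisition geometry; `fit()` runs the full estimation chain and returns
a `WavefrontResults` carrying the phase map, its Zernike decomposition, the
derived refraction, and diagnostics, with a ``summary()`` table in the style
of statistical modelling packages.

Example
-------
>>> from wfpi import simulate as sim
>>> from wfpi.model import WavefrontModel
>>> cfg = sim.SimulationConfig(grid_size=128)
>>> truth = sim.phase_from_refraction(1.0, 0.0, 0.0, cfg)
>>> model = WavefrontModel.from_simulation(truth, cfg, k=40)
>>> res = model.fit()
>>> round(res.refraction.M, 1)
1.0
"""

from __future__ import annotations

import numpy as np

from . import pipeline, zernike
from .core import recover_gradients, scale_gradients
from .types import GradientField, IntensityImage, PhaseMap, ScaleParams


class WavefrontModel:
    """Phase-retrieval model for one two-plane intensity acquisition.

    Parameters
    ----------
    i1, i2 : the intensity images at −Δz and +Δz.
    pixel_size : sensor pixel pitch s (m).
    delta_z : half-separation Δz between each plane and the pupil (m).
    magnification : pupil-to-sensor magnification (pupil pitch = s/mag).
    k : number of discrete line angles (the reference bench saw no benefit
        beyond 120).
    n_terms : Zernike terms for the analysis stage.
    """

    def __init__(self, i1: IntensityImage, i2: IntensityImage, *,
                 pixel_size: float, delta_z: float, magnification: float = 1.0,
                 k: int = 120, n_terms: int = zernike.N_TERMS_DEFAULT):
        if i1.shape != i2.shape:
            raise ValueError("the two intensity images must share a shape")
        self.i1 = i1
        self.i2 = i2
        self.params = ScaleParams(s=pixel_size, delta_z=delta_z,
                                  magnification=magnification)
        self.k = k
        self.n_terms = n_terms

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_tiff(cls, path1, path2, *, pixel_size: float, delta_z: float,
                  magnification: float = 1.0, **kw) -> "WavefrontModel":
        from .io import read_intensity
        i1 = read_intensity(path1, pixel_size=pixel_size, plane_offset=-delta_z)
        i2 = read_intensity(path2, pixel_size=pixel_size, plane_offset=+delta_z)
        return cls(i1, i2, pixel_size=pixel_size, delta_z=delta_z,
                   magnification=magnification, **kw)

    @classmethod
    def from_simulation(cls, phase: PhaseMap, config, *, seed: int | None = None,
                        **kw) -> "WavefrontModel":
        from . import simulate as sim
        i1, i2 = sim.simulate_pair(phase, config, seed=seed)
        model = cls(i1, i2, pixel_size=config.pixel_pitch,
                    delta_z=config.delta_z, **kw)
        model.ground_truth = phase
        return model

    # -- estimation -----------------------------------------------------
    def fit(self, pupil: np.ndarray | None = None) -> "WavefrontResults":
        """Run the full chain and return the results object."""
        grads = recover_gradients(self.i1, self.i2, self.k)
        scaled = scale_gradients(grads, self.params)
        phase = pipeline.reconstruct(self.i1, self.i2, self.params,
                                     k=self.k, pupil=pupil)
        report = pipeline.analyze_eye(phase, n_terms=self.n_terms)
        return WavefrontResults(self, gradients=scaled, phase=phase,
                                report=report)


class WavefrontResults:
    """Fitted wavefront: phase map, Zernike decomposition and diagnostics."""

    def __init__(self, model: WavefrontModel, gradients: GradientField,
                 phase: PhaseMap, report: pipeline.AnalysisReport):
        self.model = model
        self.gradients = gradients
        self.phase = phase
        self.report = report

    # convenient views
    @property
    def zernikes(self) -> zernike.ZernikeCoeffs:
        return self.report.coeffs

    @property
    def refraction(self) -> zernike.SpheroCylinder:
        return self.report.refraction

    @property
    def band_rms(self) -> dict[str, float]:
        return self.report.band_rms()

    @property
    def curl_rms(self) -> float:
        return getattr(self.phase, "curl_rms", float("nan"))

    def highpass(self, sigma: float = 0.5) -> PhaseMap:
        return pipeline.highpass(self.report.cropped, sigma)

    def resample(self, shape: tuple[int, int]) -> PhaseMap:
        return zernike.resample_phase(self.report.cropped, shape)

    def compare(self, other: PhaseMap) -> dict[str, float]:
        """RMS/P–V/max difference vs a reference map, modulo piston/tip/tilt
        over the common support."""
        common = self.report.cropped.mask & other.mask
        a = PhaseMap(self.report.cropped.values, common,
                     self.phase.pixel_pitch).remove_piston_tilt()
        b = PhaseMap(other.values, common, other.pixel_pitch).remove_piston_tilt()
        return pipeline.metrics(a, b)

    def summary(self) -> str:
        """Human-readable summary table of the fitted wavefront."""
        r = self.report
        sc = r.refraction
        lines = [
            "Wavefront phase imaging results",
            "=" * 46,
            f"{'pupil diameter':28s} {r.pupil_diameter_mm:8.3f} mm",
            f"{'Zernike terms':28s} {self.model.n_terms:8d}",
            f"{'line angles k':28s} {self.model.k:8d}",
            "-" * 46,
            f"{'sphere M':28s} {sc.M:+8.3f} D",
            f"{'cylinder':28s} {sc.cylinder:+8.3f} D",
            f"{'axis':28s} {sc.axis:8.1f} deg",
            f"{'J0 / J45':28s} {sc.J0:+6.3f} / {sc.J45:+6.3f} D",
            "-" * 46,
            f"{'RMS low (j 3-5)':28s} {r.rms_low:8.4f} um",
            f"{'RMS medium (j 6-14)':28s} {r.rms_medium:8.4f} um",
            f"{'RMS high (j 15-65)':28s} {r.rms_high:8.4f} um",
            f"{'RMS total (j 3-65)':28s} {r.rms_total:8.4f} um",
            f"{'P-V':28s} {r.pv:8.4f} um",
            f"{'residual vs 66-term fit':28s} {r.diff_rms:8.4f} um RMS",
            f"{'beyond 66-term basis':28s} {str(r.excess_high_frequency):>8s}",
            "-" * 46,
            f"{'curl residual':28s} {self.curl_rms:8.3e}",
            f"{'integration residual':28s} "
            f"{getattr(self.phase, 'integration_residual', float('nan')):8.3e}",
        ]
        return "\n".join(lines)

    def plot_phase(self, ax=None):
        """Quick-look rendering of the cropped phase map (µm)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.report.cropped.masked(), cmap="RdBu_r")
        ax.figure.colorbar(im, ax=ax, label="optical path (um)")
        ax.set_title("reconstructed wavefront")
        return ax
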