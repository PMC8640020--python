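"""Phase-gradient recovery from two defocused intensity images.

The sensor model: a wavefront W at the pupil displaces each geometric ray
laterally by ∓Δz·∇W at the two acquisition planes, so flux is redistributed
between I1 (at −Δz) and I2 (at +Δz).  Along any straight line through the
images, the running cumulative flux profiles of I1 and I2 are two
non-decreasing curves whose horizontal offset at equal accumulated flux is
the 1-D optimal-transport displacement of the flux along that line.  Scanning
a fan of k discrete angles and combining the per-line displacements with
their direction cosines yields the two orthogonal gradient components at
every pixel.

Displacement sign convention: positive displacement means flux moved toward
increasing line parameter going from I1 to I2, so the recovered gradient has
the sign of ∇W when I1 is the −Δz plane.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .types import AngleGrid, GradientField, IntensityImage, LineProfile, ScaleParams

#: relative flux threshold below which a profile sample carries no reliable
#: displacement information (fraction of the line's total flux per step)
EPS_FLUX = 1e-6


# ----------------------------------------------------------------------
# line families
# ----------------------------------------------------------------------

def _line_family(shape: tuple[int, int], angle: float,
                 bbox: tuple[int, int, int, int] | None = None):
    """Sampling geometry of the family of parallel lines at one angle.

    Lines are parameterised by the major axis (x for |α| ≤ π/4, else y) at
    unit steps, one line per unit intercept along the minor axis, covering
    every pixel of the region of interest (``bbox`` = (rmin, rmax, cmin,
    cmax) inclusive; the whole grid by default).  Returns (cols, rows)
    sample coordinate arrays of shape (n_lines, n_samples), the per-step
    vector ``v`` (dx, dy), and the unit direction of the line.
    """
    nrows, ncols = shape
    if bbox is None:
        rmin, rmax, cmin, cmax = 0, nrows - 1, 0, ncols - 1
    else:
        rmin, rmax, cmin, cmax = bbox
    tan = math.tan(angle)
    if abs(tan) <= 1.0:  # x-major
        x = np.arange(cmin, cmax + 1, dtype=float)
        lo = math.ceil(rmin - max(tan * cmin, tan * cmax))
        hi = math.floor(rmax - min(tan * cmin, tan * cmax))
        y0 = np.arange(lo, hi + 1, dtype=float)
        cols = np.broadcast_to(x, (y0.size, x.size)).copy()
        rows = y0[:, None] + tan * x[None, :]
        v = (1.0, tan)
    else:  # y-major
        cot = 1.0 / tan
        y = np.arange(rmin, rmax + 1, dtype=float)
        lo = math.ceil(cmin - max(cot * rmin, cot * rmax))
        hi = math.floor(cmax - min(cot * rmin, cot * rmax))
        x0 = np.arange(lo, hi + 1, dtype=float)
        rows = np.broadcast_to(y, (x0.size, y.size)).copy()
        cols = x0[:, None] + cot * y[None, :]
        v = (cot, 1.0)
    norm = math.hypot(*v)
    unit = (v[0] / norm, v[1] / norm)
    return cols, rows, v, unit


def _sample_lines(values: np.ndarray, cols: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Bilinear samples of an image along a line family; off-grid reads 0."""
    return ndimage.map_coordinates(values, [rows.ravel(), cols.ravel()],
                                   order=1, mode="constant", cval=0.0
                                   ).reshape(cols.shape)


def line_cumulative_transform(image: IntensityImage, angle: float) -> list[LineProfile]:
    """Cumulative flux profiles of one line family of an intensity image.

    One profile per parallel line at the given angle; each is the running sum
    of bilinearly interpolated image values at unit steps of the line's major
    axis, hence non-decreasing.
    """
    if not (-np.pi / 2 < angle <= np.pi / 2):
        raise ValueError(f"angle must lie in (-pi/2, pi/2], got {angle}")
    cols, rows, _, _ = _line_family(image.shape, angle)
    samples = np.cumsum(_sample_lines(image.values, cols, rows), axis=1)
    out = []
    for i in range(cols.shape[0]):
        positions = np.column_stack([rows[i], cols[i]])
        out.append(LineProfile(line_id=(0, i), samples=samples[i], positions=positions))
    return out


# ----------------------------------------------------------------------
# 1-D transport matching
# ----------------------------------------------------------------------

def _invert_profiles(F: np.ndarray, G: np.ndarray, eps: float = EPS_FLUX):
    """Per-row transport displacement between cumulative profile stacks.

    For each row i and sample t, returns the transport displacement
    ``d[i, t] = G_i^{-1}(v) - t`` of sample t's flux, where the inverse is
    monotone piecewise-linear interpolation after normalising both profiles
    to a common total.  The query uses the mass-centre convention: v is the
    half-mass quantile (F(t-1)+F(t))/2 and the CDF knots sit at
    half-integer positions (sample t's flux spread over (t-1/2, t+1/2)), so
    identical profiles give exactly zero displacement at every sample.
    Flat runs of G invert to their interval midpoint.  ``valid`` flags
    samples whose local F slope exceeds ``eps`` times the line total (and
    whose line has flux in both profiles).
    """
    F = np.asarray(F, dtype=float)
    G = np.asarray(G, dtype=float)
    n, T = F.shape
    totF = F[:, -1]
    totG = G[:, -1]
    # lines carrying less than 1e-9 of the strongest line are numerical dust
    # (splat residue just outside the pupil), not signal
    line_ok = ((totF > 1e-9 * totF.max(initial=0.0))
               & (totG > 1e-9 * totG.max(initial=0.0)))
    safeF = np.where(line_ok, totF, 1.0)
    safeG = np.where(line_ok, totG, 1.0)
    Fn = np.where(line_ok[:, None], F / safeF[:, None], 0.0)
    Gn = np.where(line_ok[:, None], G / safeG[:, None], 0.0)

    slope = np.diff(Fn, axis=1, prepend=0.0)
    valid = line_ok[:, None] & (slope > eps)

    # offset each row into a disjoint ascending band so one global
    # searchsorted handles every line at once
    off = 2.0 * np.arange(n)[:, None]
    gflat = (Gn + off).ravel()
    q = (Fn - 0.5 * slope + off).ravel()  # half-mass quantile of sample t
    left = np.searchsorted(gflat, q, side="left")
    right = np.searchsorted(gflat, q, side="right")

    row_start = np.repeat(np.arange(n) * T, T)
    x = np.empty(n * T)

    exact = right > left
    x[exact] = 0.5 * (left[exact] + right[exact] - 1) - row_start[exact]

    between = ~exact
    ib = left[between]
    at_start = ib == row_start[between]
    # v < G[0]: linear from the virtual origin (position -1, value 0)
    gb = Gn.ravel()
    qb = (Fn - 0.5 * slope).ravel()[between]
    xb = np.empty(ib.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        g0 = gb[ib[at_start]]
        xb[at_start] = qb[at_start] / np.where(g0 > 0, g0, 1.0) - 1.0
        lo = gb[np.maximum(ib - 1, 0)]
        hi = gb[np.minimum(ib, n * T - 1)]
        frac = (qb - lo) / np.where(hi > lo, hi - lo, 1.0)
        interior = ~at_start
        xb[interior] = (ib[interior] - 1 - row_start[between][interior]
                        + frac[interior])
    x[between] = xb

    # +0.5 converts integer-knot interpolation to half-integer knot positions
    d = x.reshape(n, T) + 0.5 - np.arange(T)[None, :]
    d[~valid] = 0.0
    return d, valid


def displacement_between_profiles(f: LineProfile, g: LineProfile):
    """1-D transport displacement (pixels of the major axis) from f to g.

    Positive where flux moves toward increasing positions.  Samples where f
    carries negligible flux are flagged invalid; a zero-total profile makes
    every sample invalid.
    """
    if f.samples.shape != g.samples.shape:
        raise ValueError("profiles must share a parameterisation axis")
    d, valid = _invert_profiles(f.samples[None, :], g.samples[None, :])
    return d[0], valid[0]


# ----------------------------------------------------------------------
# gradient recovery
# ----------------------------------------------------------------------

def transport_image(values: np.ndarray, disp_r: np.ndarray,
                    disp_c: np.ndarray) -> np.ndarray:
    """Mass-conserving transport of an image by a per-pixel displacement.

    Each pixel's flux is deposited at its displaced position by bilinear
    splatting; destinations are clamped to the grid so total flux is
    conserved exactly.
    """
    nrows, ncols = values.shape
    r0, c0 = np.nonzero(values > 0)
    f = values[r0, c0]
    rr = np.clip(r0 + disp_r[r0, c0], 0.0, nrows - 1.0)
    cc = np.clip(c0 + disp_c[r0, c0], 0.0, ncols - 1.0)
    ri = np.floor(rr).astype(np.int64)
    ci = np.floor(cc).astype(np.int64)
    fr = rr - ri
    fc = cc - ci
    out = np.zeros(nrows * ncols)
    for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc),
                      (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
        idx = (np.minimum(ri + dr, nrows - 1) * ncols
               + np.minimum(ci + dc, ncols - 1))
        out += np.bincount(idx, weights=f * w, minlength=out.size)
    return out.reshape(nrows, ncols)


def _measure_displacements(v1: np.ndarray, v2: np.ndarray, angles: AngleGrid,
                           eps_flux: float, min_weight_frac: float):
    """One application of the fan-transport measurement operator.

    For every discrete angle both images are reduced to families of
    cumulative line profiles, the per-line transport displacements are
    measured, converted to arc-length and deposited at the source/destination
    midpoint by bilinear splatting.  Each pixel then combines its angular
    projections by weighted least squares — the cos(α)/sin(α)-weighted sums
    with the exact normal-matrix normalisation — giving displacement
    components along x (toward +columns) and y (toward +rows) in pixels.
    """
    shape = v1.shape
    nrows, ncols = shape

    # restrict line families to the flux-carrying region
    carrier = (v1 > 0) | (v2 > 0)
    if not carrier.any():
        zeros = np.zeros(shape)
        return zeros, zeros.copy(), np.zeros(shape, dtype=bool), zeros.copy()
    crows = np.nonzero(carrier.any(axis=1))[0]
    ccols = np.nonzero(carrier.any(axis=0))[0]
    pad = 2
    bbox = (max(int(crows[0]) - pad, 0), min(int(crows[-1]) + pad, nrows - 1),
            max(int(ccols[0]) - pad, 0), min(int(ccols[-1]) + pad, ncols - 1))

    a11 = np.zeros(shape)
    a12 = np.zeros(shape)
    a22 = np.zeros(shape)
    b1 = np.zeros(shape)
    b2 = np.zeros(shape)
    wsum = np.zeros(shape)
    size = nrows * ncols

    for angle in angles.angles:
        cols, rows, v, unit = _line_family(shape, angle, bbox)
        step = math.hypot(*v)
        s1 = _sample_lines(v1, cols, rows)
        s2 = _sample_lines(v2, cols, rows)
        F = np.cumsum(s1, axis=1)
        G = np.cumsum(s2, axis=1)
        d, valid = _invert_profiles(F, G, eps_flux)
        if not valid.any():
            continue
        dv = d[valid]
        proj = dv * step  # arc-length displacement along the line
        # each sample is weighted by the flux it transports: low-flux
        # chord-end samples carry the least reliable displacements
        wflux = s1[valid]
        # midpoint between source and destination = pupil-plane position
        mc = cols[valid] + 0.5 * dv * v[0]
        mr = rows[valid] + 0.5 * dv * v[1]

        inside = (mc > -1) & (mc < ncols) & (mr > -1) & (mr < nrows)
        mc, mr, proj, wflux = mc[inside], mr[inside], proj[inside], wflux[inside]
        c0 = np.floor(mc).astype(np.int64)
        r0 = np.floor(mr).astype(np.int64)
        fc = mc - c0
        fr = mr - r0
        ux, uy = unit
        for dr, dc, w in ((0, 0, (1 - fr) * (1 - fc)), (0, 1, (1 - fr) * fc),
                          (1, 0, fr * (1 - fc)), (1, 1, fr * fc)):
            rr = r0 + dr
            cc = c0 + dc
            ok = (rr >= 0) & (rr < nrows) & (cc >= 0) & (cc < ncols)
            idx = (rr[ok] * ncols + cc[ok])
            wv = w[ok] * wflux[ok]
            wp = wv * proj[ok]
            wsum.ravel()[:] += np.bincount(idx, weights=wv, minlength=size)
            a11.ravel()[:] += np.bincount(idx, weights=wv * ux * ux, minlength=size)
            a12.ravel()[:] += np.bincount(idx, weights=wv * ux * uy, minlength=size)
            a22.ravel()[:] += np.bincount(idx, weights=wv * uy * uy, minlength=size)
            b1.ravel()[:] += np.bincount(idx, weights=wp * ux, minlength=size)
            b2.ravel()[:] += np.bincount(idx, weights=wp * uy, minlength=size)

    det = a11 * a22 - a12 ** 2
    covered = wsum > 0
    if not covered.any():
        zeros = np.zeros(shape)
        return zeros, zeros.copy(), np.zeros(shape, dtype=bool), wsum
    w_thresh = min_weight_frac * float(np.median(wsum[covered]))
    # require a reasonably isotropic angular sampling at the pixel
    mask = (wsum >= w_thresh) & (det >= 0.05 * (0.5 * wsum) ** 2)
    gh = np.zeros(shape)
    gv = np.zeros(shape)
    safe_det = np.where(mask, det, 1.0)
    gh[mask] = ((a22 * b1 - a12 * b2) / safe_det)[mask]
    gv[mask] = ((a11 * b2 - a12 * b1) / safe_det)[mask]
    return gh, gv, mask, wsum


class _GradientBasis:
    """Analytic gradient basis of Zernike modes over the whole grid.

    Used by the iterative refinement to represent displacement fields as
    smooth, curl-free wavefront gradients: columns are (∂Z_j/∂x, ∂Z_j/∂y)
    sampled on the pixel grid for OSA modes j = 1…n_terms−1 on the circle
    (center, radius).  Polynomials extrapolate smoothly past the pupil rim,
    which is exactly what warping needs there.
    """

    def __init__(self, shape: tuple[int, int], center: tuple[float, float],
                 radius: float, n_terms: int = 66):
        from .zernike import zernike_values  # deferred: zernike imports types only
        rows, cols = np.indices(shape, dtype=float)
        x = (cols - center[1]) / radius
        y = (center[0] - rows) / radius  # y up, matching the analysis frame
        rho = np.hypot(x, y)
        theta = np.arctan2(y, x)
        self.shape = shape
        self.modes = list(range(1, n_terms))
        self.dzdx = []
        self.dzdy = []
        for j in self.modes:
            z = zernike_values(j, rho, theta)
            gy, gx = np.gradient(z)  # per pixel step
            self.dzdx.append(gx)
            self.dzdy.append(gy)

    def fit(self, gh: np.ndarray, gv: np.ndarray, sel: np.ndarray,
            weight: np.ndarray | None = None) -> np.ndarray:
        """Weighted LSQ coefficients of a displacement field on the basis."""
        w = np.ones(int(sel.sum())) if weight is None else weight[sel]
        w = np.sqrt(np.maximum(w, 0.0))
        design = np.empty((2 * w.size, len(self.modes)))
        for i, (dx, dy) in enumerate(zip(self.dzdx, self.dzdy)):
            design[:w.size, i] = dx[sel] * w
            design[w.size:, i] = dy[sel] * w
        target = np.concatenate([gh[sel] * w, gv[sel] * w])
        coeffs, *_ = np.linalg.lstsq(design, target, rcond=None)
        return coeffs

    def synth(self, coeffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        gh = np.zeros(self.shape)
        gv = np.zeros(self.shape)
        for c, dx, dy in zip(coeffs, self.dzdx, self.dzdy):
            if c != 0.0:
                gh += c * dx
                gv += c * dy
        return gh, gv


def recover_gradients(i1: IntensityImage, i2: IntensityImage,
                      angles: AngleGrid | int = 120,
                      eps_flux: float = EPS_FLUX,
                      min_weight_frac: float = 0.3,
                      n_iter: int = 6,
                      relax: float = 0.7,
                      tol: float = 1e-4) -> GradientField:
    """Recover the horizontal/vertical phase-gradient maps in pixel units.

    The fan-transport operator (see :func:`_measure_displacements`) is exact
    for flux that moves rigidly along each line family, but where flux
    converges or diverges across lines (defocus-like flow) a single
    application overestimates the displacement radially.  The recovery is
    therefore applied iteratively: after each measurement both images are
    warped half-way toward the pupil plane with the current estimate
    (conservative bilinear transport, the estimate extended past its mask by
    nearest-neighbour fill so the rim annulus of the expanded image warps
    back too) and the residual displacement is re-measured and accumulated
    under relaxation ``relax`` — near-tangent chords at the pupil rim can
    more than double the local measurement gain, so a full-step update is
    unstable there.  The default 6 passes leave well under 1 % of the
    initial bias.  ``n_iter=1`` is the plain one-shot operator.

    Returns displacements in pixels: grad_h toward +columns, grad_v toward
    +rows, positive for flux moving that way from I1 (−Δz) to I2 (+Δz).
    The mask is false where the accumulated splat weight falls below
    ``min_weight_frac`` of the median coverage or the angular sampling is
    too one-sided to invert.
    """
    if isinstance(angles, int):
        angles = AngleGrid(angles)
    if i1.shape != i2.shape:
        raise ValueError("the two intensity images must share a shape")
    if angles.k < 2:
        raise ValueError("need at least 2 angles")
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")

    rr, cc = np.indices(i1.shape, dtype=float)
    nrows, ncols = i1.shape

    def _halfway(values: np.ndarray, ghf: np.ndarray, gvf: np.ndarray,
                 sign: float) -> np.ndarray:
        # displacement field is defined at the pupil plane; one Picard step
        # evaluates it at the displaced position for second-order accuracy
        coords = [np.clip(rr + sign * 0.5 * gvf, 0, nrows - 1).ravel(),
                  np.clip(cc + sign * 0.5 * ghf, 0, ncols - 1).ravel()]
        dr = sign * 0.5 * ndimage.map_coordinates(gvf, coords, order=1
                                                  ).reshape(values.shape)
        dc = sign * 0.5 * ndimage.map_coordinates(ghf, coords, order=1
                                                  ).reshape(values.shape)
        return transport_image(values, dr, dc)

    gh, gv, mask, wsum = _measure_displacements(
        i1.values, i2.values, angles, eps_flux, min_weight_frac)
    if n_iter == 1 or not mask.any():
        return GradientField(grad_h=gh, grad_v=gv, mask=mask, units="pixels",
                             weight=wsum)

    # The refinement corrects the smooth transport bias, so it tracks a
    # parametric warp field: the estimate projected on the analytic gradient
    # basis of the first 66 Zernike modes over the detected pupil.  Warping
    # with the raw per-pixel estimate would re-inject its rim sampling
    # artifacts into every chord of the warped images; the polynomial field
    # is smooth across (and beyond) the rim by construction.
    from .zernike import largest_inscribed_circle
    center, radius = largest_inscribed_circle(mask)
    basis = _GradientBasis(i1.shape, center, radius)
    coeffs = basis.fit(gh, gv, mask, wsum)
    tilt = coeffs[:2].copy()
    corr = np.zeros_like(coeffs)
    for _ in range(n_iter - 1):
        ghf, gvf = basis.synth(coeffs + corr)
        w1 = _halfway(i1.values, ghf, gvf, +1.0)
        w2 = _halfway(i2.values, ghf, gvf, -1.0)
        rh, rv, rmask, _ = _measure_displacements(
            w1, w2, angles, eps_flux, min_weight_frac)
        upd = mask & rmask
        if not upd.any():
            break
        delta = basis.fit(rh, rv, upd, wsum)
        # the one-shot operator is exact for rigid shifts; re-measuring
        # images warped by an imperfect field rectifies its errors into a
        # spurious rigid component, so tip/tilt is frozen at the first pass
        delta[:2] = 0.0
        corr += relax * delta
        if np.abs(delta).max() < tol:
            break
    corr_h, corr_v = basis.synth(corr)
    return GradientField(grad_h=gh + corr_h, grad_v=gv + corr_v, mask=mask,
                         units="pixels", weight=wsum)


def scale_gradients(g: GradientField, p: ScaleParams) -> GradientField:
    """Convert pixel-unit gradients to metres of optical path per pixel step.

    Multiplies both components by s²/(2Δz): a displacement of one pixel
    between planes separated by 2Δz corresponds to a wavefront slope of
    s/(2Δz), i.e. s²/(2Δz) metres of optical path per pixel step.
    """
    if g.units != "pixels":
        raise ValueError("gradient field is already in metric units")
    factor = p.s ** 2 / (2.0 * p.delta_z)
    return GradientField(grad_h=g.grad_h * factor, grad_v=g.grad_v * factor,
                         mask=g.mask.copy(), units="metres", weight=g.weight)
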