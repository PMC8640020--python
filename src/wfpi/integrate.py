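"""Least-squares integration of a gradient field over an arbitrary pupil.

The phase is the exact minimiser of the discrete least-squares problem

    min_W Σ |W[i, j+1] − W[i, j] − ½(gh[i, j] + gh[i, j+1])|²
        + Σ |W[i+1, j] − W[i, j] − ½(gv[i, j] + gv[i, j+1])|²

over all pixel pairs inside the mask, i.e. the staggered (second-order)
forward-difference model.  The normal equations form a masked graph
Laplacian which is solved directly with a sparse factorisation; the
constant (piston) nullspace is pinned and removed afterwards, so the
returned phase has zero mean over the mask.  Works on any connected,
possibly non-circular pupil without boundary padding heuristics.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .types import GradientField, PhaseMap


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 16:
        raise ValueError("mask must contain at least 16 pixels")
    _, ncomp = ndimage.label(mask)
    if ncomp != 1:
        raise ValueError(f"mask must be a single connected component, got {ncomp}")
    return mask


def integrate_gradients(g: GradientField, mask: np.ndarray | None = None,
                        pixel_pitch: float | None = None) -> PhaseMap:
    """Integrate a metric gradient field into a phase map (µm) over a mask.

    Parameters
    ----------
    g : gradient field in metres of optical path per pixel step.
    mask : pupil support; must be connected and contained in ``g.mask``.
        Defaults to ``g.mask`` itself (restricted to its largest component).
    pixel_pitch : metres per pixel in the pupil plane, carried into the
        returned :class:`PhaseMap`.

    Returns the least-squares phase with piston removed (zero mean over the
    mask).  The RMS of the residual between the phase's discrete gradients
    and the input field is stored on the result as ``integration_residual``.
    """
    if g.units != "metres":
        raise ValueError("integrate expects gradients in metric units; "
                         "apply scale_gradients first")
    if mask is None:
        lab, n = ndimage.label(g.mask)
        if n == 0:
            raise ValueError("empty gradient mask")
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    mask = _check_mask(mask)
    if np.any(mask & ~g.mask):
        raise ValueError("mask must be contained in the gradient validity mask")

    nrows, ncols = mask.shape
    index = -np.ones(mask.shape, dtype=np.int64)
    index[mask] = np.arange(int(mask.sum()))
    npx = int(mask.sum())

    rows_i, rows_j, data, rhs = [], [], [], []
    eq = 0

    def add_pairs(m_a, m_b, gmean):
        nonlocal eq
        ia = index[m_a]
        ib = index[m_b]
        n = ia.size
        rows_i.append(np.repeat(np.arange(eq, eq + n), 2))
        rows_j.append(np.column_stack([ib, ia]).ravel())
        data.append(np.tile([1.0, -1.0], n))
        rhs.append(gmean)
        eq += n

    # horizontal pairs (i, j) - (i, j+1)
    ph = mask[:, :-1] & mask[:, 1:]
    a = np.zeros_like(mask)
    b = np.zeros_like(mask)
    a[:, :-1] = ph
    b[:, 1:] = ph
    add_pairs(a, b, 0.5 * (g.grad_h[a] + g.grad_h[b]))
    # vertical pairs (i, j) - (i+1, j)
    pv = mask[:-1, :] & mask[1:, :]
    a = np.zeros_like(mask)
    b = np.zeros_like(mask)
    a[:-1, :] = pv
    b[1:, :] = pv
    add_pairs(a, b, 0.5 * (g.grad_v[a] + g.grad_v[b]))

    A = sparse.csr_matrix(
        (np.concatenate(data),
         (np.concatenate(rows_i), np.concatenate(rows_j))),
        shape=(eq, npx))
    bvec = np.concatenate(rhs)
    # pin the piston nullspace; the exact value is irrelevant once the mean
    # is removed
    pin = sparse.csr_matrix(([1.0], ([0], [0])), shape=(npx, npx))
    lhs = (A.T @ A + pin).tocsc()
    rhs_n = A.T @ bvec
    w = spsolve(lhs, rhs_n)
    w -= w.mean()

    resid = A @ w - bvec
    values = np.zeros(mask.shape)
    values[mask] = w * 1e6  # metres -> micrometres
    phase = PhaseMap(values=values, mask=mask,
                     pixel_pitch=pixel_pitch if pixel_pitch is not None else 1.0)
    phase.integration_residual = float(np.sqrt(np.mean(resid ** 2)))
    return phase


def differentiate(phase: PhaseMap) -> GradientField:
    """Discrete gradients (metres per pixel step) of a phase map.

    Central differences in the interior of the mask, one-sided at the rim;
    the inverse of :func:`integrate_gradients` up to least-squares residual.
    """
    w = np.where(phase.mask, phase.values * 1e-6, np.nan)
    gh = np.full(w.shape, np.nan)
    gv = np.full(w.shape, np.nan)
    # central
    gh[:, 1:-1] = 0.5 * (w[:, 2:] - w[:, :-2])
    gv[1:-1, :] = 0.5 * (w[2:, :] - w[:-2, :])
    # one-sided fallback where central hits the rim
    fwd_h = np.full(w.shape, np.nan)
    fwd_h[:, :-1] = w[:, 1:] - w[:, :-1]
    bwd_h = np.full(w.shape, np.nan)
    bwd_h[:, 1:] = w[:, 1:] - w[:, :-1]
    gh = np.where(np.isnan(gh), fwd_h, gh)
    gh = np.where(np.isnan(gh), bwd_h, gh)
    fwd_v = np.full(w.shape, np.nan)
    fwd_v[:-1, :] = w[1:, :] - w[:-1, :]
    bwd_v = np.full(w.shape, np.nan)
    bwd_v[1:, :] = w[1:, :] - w[:-1, :]
    gv = np.where(np.isnan(gv), fwd_v, gv)
    gv = np.where(np.isnan(gv), bwd_v, gv)
    mask = phase.mask & np.isfinite(gh) & np.isfinite(gv)
    gh = np.where(mask, gh, 0.0)
    gv = np.where(mask, gv, 0.0)
    return GradientField(grad_h=gh, grad_v=gv, mask=mask, units="metres")


def curl_residual(g: GradientField, mask: np.ndarray | None = None) -> float:
    """RMS of the discrete curl ∂gh/∂y − ∂gv/∂x over the mask interior.

    Zero (to rounding) for any exact gradient field; a useful consistency
    diagnostic for measured fields before integration.
    """
    if mask is None:
        mask = g.mask
    mask = np.asarray(mask, dtype=bool)
    interior = ndimage.binary_erosion(mask)
    if not interior.any():
        raise ValueError("mask has no interior pixels")
    dgh_dy = np.zeros(mask.shape)
    dgv_dx = np.zeros(mask.shape)
    dgh_dy[1:-1, :] = 0.5 * (g.grad_h[2:, :] - g.grad_h[:-2, :])
    dgv_dx[:, 1:-1] = 0.5 * (g.grad_v[:, 2:] - g.grad_v[:, :-2])
    curl = dgh_dy[interior] - dgv_dx[interior]
    return float(np.sqrt(np.mean(curl ** 2)))
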