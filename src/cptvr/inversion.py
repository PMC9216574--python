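"""Regularized reconstruction of the traction field from displacements.

The inverse problem  min_t ||G t - u||^2 + lambda ||t||^2  is solved for
the discretized Boussinesq operator G on a regular grid.  Two solvers are
provided:

* ``solver='direct'`` — dense assembly of G (analytic per-cell integrals,
  identical to the forward model of :mod:`cptvr.benchmark`) and a
  regularized least-squares solve.  Reference implementation; practical
  up to roughly 48 x 48 grids.
* ``solver='fourier'`` — per-wavevector Tikhonov inversion of the
  periodic (Fourier-space) Boussinesq kernel, the classic regularized
  Fourier-transform traction cytometry scheme.  Fast at any grid size;
  approximates the field as periodic.

The regularization weight is either fixed or chosen by the L-curve
corner (maximum curvature of the log residual-norm vs log solution-norm
trade-off curve).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import griddata

from .benchmark import ElasticHalfSpace, TractionField, _rect_greens_integrals
from .tracking import DisplacementField

__all__ = [
    "RegularizationSpec",
    "interpolate_to_grid",
    "assemble_greens_matrix",
    "reconstruct_traction",
    "select_lambda_lcurve",
    "fourier_kernel",
]


@dataclass
class RegularizationSpec:
    """L2 (Tikhonov) regularization setup."""

    lam: float = 1e-4
    selection: str = "fixed"  # or "l_curve"
    lambda_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if np.any(g <= 0) or np.any(np.diff(g) <= 0):
                raise ValueError("lambda_grid must be strictly positive and sorted")
            self.lambda_grid = g


def default_lambda_grid(n: int = 20) -> np.ndarray:
    """20 log-spaced values spanning 1e-6 .. 1e2 times the operator scale."""
    return np.logspace(-6, 2, n)


def interpolate_to_grid(
    field_in: DisplacementField,
    grid_shape: tuple[int, int],
    fov_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scattered-to-grid linear interpolation of the confident vectors.

    Returns (ug, vg, spacing): displacement components on a
    ``grid_shape`` grid spanning the field of view, with points outside
    the convex hull of the data set to zero, and the grid spacing in px.
    """
    conf = field_in.confident_mask()
    pts = field_in.origins[conf]
    vec = field_in.vectors[conf]
    if pts.shape[0] < 3:
        raise ValueError("need >= 3 confident vectors to interpolate")
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise ValueError("confident vectors are collinear; cannot interpolate")
    gh, gw = grid_shape
    h, w = fov_shape
    spacing = w / gw
    gx = (np.arange(gw) + 0.5) * spacing - 0.5
    gy = (np.arange(gh) + 0.5) * (h / gh) - 0.5
    gxx, gyy = np.meshgrid(gx, gy)
    ug = griddata(pts, vec[:, 0], (gxx, gyy), method="linear", fill_value=0.0)
    vg = griddata(pts, vec[:, 1], (gxx, gyy), method="linear", fill_value=0.0)
    return ug, vg, spacing


def assemble_greens_matrix(
    grid_shape: tuple[int, int],
    spacing: float,
    material: ElasticHalfSpace,
) -> np.ndarray:
    """Dense Boussinesq operator mapping cell tractions (Pa) to node
    displacements (px) on the same grid, using exact analytic integrals of
    the Green's function over each square cell."""
    gh, gw = grid_shape
    n = gh * gw
    ys, xs = np.mgrid[0:gh, 0:gw]
    px = xs.ravel() * spacing
    py = ys.ravel() * spacing
    dx = px[:, None] - px[None, :]
    dy = py[:, None] - py[None, :]
    a = spacing / 2.0
    i_one, i_xx, i_yy, i_xy = _rect_greens_integrals(
        dx - a, dx + a, dy - a, dy + a
    )
    nu = material.nu
    c = (1.0 + nu) / (np.pi * material.E)
    gxx = c * ((1.0 - nu) * i_one + nu * i_xx)
    gyy = c * ((1.0 - nu) * i_one + nu * i_yy)
    gxy = c * nu * i_xy
    G = np.empty((2 * n, 2 * n))
    G[0::2, 0::2] = gxx
    G[0::2, 1::2] = gxy
    G[1::2, 0::2] = gxy
    G[1::2, 1::2] = gyy
    return G


def fourier_kernel(
    grid_shape: tuple[int, int],
    spacing: float,
    material: ElasticHalfSpace,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fourier-space Boussinesq kernel components (Gxx, Gyy, Gxy) on the
    FFT frequency grid; the zero wavevector is left at zero (zero mean
    traction)."""
    gh, gw = grid_shape
    kx = 2 * np.pi * np.fft.fftfreq(gw, d=spacing)
    ky = 2 * np.pi * np.fft.fftfreq(gh, d=spacing)
    kxx, kyy = np.meshgrid(kx, ky)
    k = np.hypot(kxx, kyy)
    nu = material.nu
    E = material.E
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k**3)
        gxx = pref * ((1.0 - nu) * k**2 + nu * kyy**2)
        gyy = pref * ((1.0 - nu) * k**2 + nu * kxx**2)
        gxy = pref * (-nu * kxx * kyy)
    gxx[0, 0] = gyy[0, 0] = gxy[0, 0] = 0.0
    return gxx, gyy, gxy


def _solve_fourier(
    ug: np.ndarray,
    vg: np.ndarray,
    spacing: float,
    material: ElasticHalfSpace,
    lam: float,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Per-wavevector Tikhonov solve; returns (tx, ty, residual, norm)."""
    gxx, gyy, gxy = fourier_kernel(ug.shape, spacing, material)
    fu = np.fft.fft2(ug)
    fv = np.fft.fft2(vg)
    # normal equations of the 2x2 system per wavevector: (K^T K + lam I) t = K^T u
    a11 = gxx * gxx + gxy * gxy + lam
    a12 = gxy * (gxx + gyy)
    a22 = gyy * gyy + gxy * gxy + lam
    b1 = gxx * fu + gxy * fv
    b2 = gxy * fu + gyy * fv
    det = a11 * a22 - a12 * a12
    det = np.where(np.abs(det) > 0, det, 1.0)
    ftx = (a22 * b1 - a12 * b2) / det
    fty = (a11 * b2 - a12 * b1) / det
    tx = np.real(np.fft.ifft2(ftx))
    ty = np.real(np.fft.ifft2(fty))
    ru = np.real(np.fft.ifft2(gxx * ftx + gxy * fty)) - ug
    rv = np.real(np.fft.ifft2(gxy * ftx + gyy * fty)) - vg
    residual = float(np.sqrt((ru**2 + rv**2).sum()))
    norm = float(np.sqrt((tx**2 + ty**2).sum()))
    return tx, ty, residual, norm


def _solve_direct(
    ug: np.ndarray,
    vg: np.ndarray,
    spacing: float,
    material: ElasticHalfSpace,
    lam: float,
    G: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    gh, gw = ug.shape
    if G is None:
        G = assemble_greens_matrix((gh, gw), spacing, material)
    u = np.empty(2 * gh * gw)
    u[0::2] = ug.ravel()
    u[1::2] = vg.ravel()
    A = G.T @ G
    if lam == 0.0:
        cond = np.linalg.cond(A)
        if cond > 1e12:
            raise np.linalg.LinAlgError(
                f"unregularized normal equations are ill-conditioned (cond={cond:.2e});"
                " use lambda > 0"
            )
    A[np.diag_indices_from(A)] += lam
    t = np.linalg.solve(A, G.T @ u)
    tx = t[0::2].reshape(gh, gw)
    ty = t[1::2].reshape(gh, gw)
    residual = float(np.linalg.norm(G @ t - u))
    norm = float(np.linalg.norm(t))
    return tx, ty, residual, norm


def _lcurve_tradeoff(
    ug, vg, spacing, material, lambda_grid, solver, G=None
) -> tuple[np.ndarray, np.ndarray]:
    res = np.empty(len(lambda_grid))
    nrm = np.empty(len(lambda_grid))
    for i, lam in enumerate(lambda_grid):
        if solver == "fourier":
            _, _, res[i], nrm[i] = _solve_fourier(ug, vg, spacing, material, lam)
        else:
            _, _, res[i], nrm[i] = _solve_direct(ug, vg, spacing, material, lam, G)
    return res, nrm


def select_lambda_lcurve(
    ug: np.ndarray,
    vg: np.ndarray,
    spacing: float,
    material: ElasticHalfSpace,
    lambda_grid: np.ndarray | None = None,
    solver: str = "fourier",
) -> float:
    """L-corner selection: lambda at maximum curvature of the log-log
    (residual norm, solution norm) curve.

    Falls back (with a warning) to the point of closest approach to the
    curve's lower-left corner when no curvature maximum exists."""
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid)
    if len(grid) < 5 or np.log10(grid[-1] / grid[0]) < 3:
        raise ValueError("lambda_grid must hold >= 5 points spanning >= 3 decades")
    res, nrm = _lcurve_tradeoff(ug, vg, spacing, material, grid, solver)
    x = np.log(np.maximum(res, 1e-300))
    y = np.log(np.maximum(nrm, 1e-300))
    t = np.log(grid)
    dx = np.gradient(x, t)
    dy = np.gradient(y, t)
    ddx = np.gradient(dx, t)
    ddy = np.gradient(dy, t)
    denom = (dx**2 + dy**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = np.abs(dx * ddy - dy * ddx) / np.where(denom > 0, denom, np.inf)
    curv = np.nan_to_num(curv, nan=0.0)
    interior = slice(1, -1)
    if np.all(curv[interior] <= 0):
        import warnings

        warnings.warn(
            "L-curve has no convex corner; falling back to the closest point "
            "to the origin of the normalized trade-off curve",
            stacklevel=2,
        )
        xs = (x - x.min()) / max(np.ptp(x), 1e-12)
        ys = (y - y.min()) / max(np.ptp(y), 1e-12)
        return float(grid[np.argmin(xs**2 + ys**2)])
    k = 1 + int(np.argmax(curv[interior]))
    return float(grid[k])


def reconstruct_traction(
    ug: np.ndarray,
    vg: np.ndarray,
    spacing: float,
    material: ElasticHalfSpace,
    reg: RegularizationSpec | None = None,
    solver: str = "fourier",
    pixel_size: float = 108.0,
) -> TractionField:
    """Tikhonov-regularized inversion of the Boussinesq operator.

    Parameters
    ----------
    ug, vg : gridded displacement components (px).
    spacing : grid spacing (px).
    solver : 'fourier' (periodic approximation, any size) or 'direct'
        (dense reference solver for small grids).
    """
    reg = RegularizationSpec() if reg is None else reg
    lam = reg.lam
    if reg.selection == "l_curve":
        lam = select_lambda_lcurve(
            ug, vg, spacing, material, reg.lambda_grid, solver=solver
        )
    if solver == "fourier":
        tx, ty, _, _ = _solve_fourier(ug, vg, spacing, material, lam)
    elif solver == "direct":
        tx, ty, _, _ = _solve_direct(ug, vg, spacing, material, lam)
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return TractionField(tx=tx, ty=ty, pixel_size=pixel_size * spacing)
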