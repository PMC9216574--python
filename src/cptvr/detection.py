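"""Sub-pixel bead localization in the reference image.

Candidate beads are local maxima of a Laplacian-of-Gaussian filtered
image; each candidate is refined by fitting an isotropic 2D Gaussian
(fixed PSF width) plus a local background to the raw intensities around
it, and candidates whose fitted amplitude is not statistically
significant against the local residual noise are discarded (t-test at
level ``alpha``).

At realistic TFM bead densities neighboring point spread functions
overlap heavily; a single-Gaussian fit per local maximum is used rather
than mixture deconvolution, because downstream tracking interrogates
image templates, not isolated emitters.  Beads closer than roughly twice
the PSF width merge into one candidate and are reported once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import t as student_t

__all__ = ["Detection", "detect_beads", "detections_to_array"]


@dataclass
class Detection:
    """One localized bead."""

    position: tuple[float, float]  # (x, y), px
    amplitude: float
    fit_residual: float  # residual standard deviation in the fit window
    sigma_fit: float  # PSF sigma used by the fit, px


def _gaussian_fit_batch(
    image: np.ndarray,
    peaks_xy: np.ndarray,
    sigma: float,
    window_half: int,
    n_iter: int = 12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Gauss-Newton fit of A*G(x-x0, y-y0; sigma) + b at every peak, vectorized
    over peaks.  Returns (x0, y0, A, b, residual_sd)."""
    h, w = image.shape
    k = window_half
    size = 2 * k + 1
    m = peaks_xy.shape[0]
    # integer window anchors, clamped inside the image
    ix = np.clip(peaks_xy[:, 0].astype(int), k, w - 1 - k)
    iy = np.clip(peaks_xy[:, 1].astype(int), k, h - 1 - k)
    offs = np.arange(-k, k + 1)
    rows = iy[:, None, None] + offs[None, :, None]
    cols = ix[:, None, None] + offs[None, None, :]
    patches = image[rows, cols].reshape(m, -1)  # (m, size^2)
    gx = np.tile(offs[None, None, :], (m, size, 1)).reshape(m, -1).astype(float)
    gy = np.tile(offs[None, :, None], (m, 1, size)).reshape(m, -1).astype(float)

    x0 = np.zeros(m)
    y0 = np.zeros(m)
    amp = np.maximum(patches.max(axis=1) - np.median(patches, axis=1), 1e-6)
    bg = np.median(patches, axis=1)
    inv2s2 = 1.0 / (2.0 * sigma**2)
    for _ in range(n_iter):
        dx = gx - x0[:, None]
        dy = gy - y0[:, None]
        g = np.exp(-(dx**2 + dy**2) * inv2s2)
        model = amp[:, None] * g + bg[:, None]
        r = patches - model
        # Jacobian columns: dA, db, dx0, dy0
        j_a = g
        j_b = np.ones_like(g)
        j_x = amp[:, None] * g * dx * (2.0 * inv2s2)
        j_y = amp[:, None] * g * dy * (2.0 * inv2s2)
        J = np.stack([j_a, j_b, j_x, j_y], axis=2)  # (m, n, 4)
        JtJ = np.einsum("mni,mnj->mij", J, J)
        Jtr = np.einsum("mni,mn->mi", J, r)
        JtJ += 1e-9 * np.eye(4)[None]
        try:
            step = np.linalg.solve(JtJ, Jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("mij,mj->mi", np.linalg.pinv(JtJ), Jtr)
        amp = amp + step[:, 0]
        bg = bg + step[:, 1]
        x0 = np.clip(x0 + step[:, 2], -1.5, 1.5)
        y0 = np.clip(y0 + step[:, 3], -1.5, 1.5)
        amp = np.maximum(amp, 1e-9)
    dx = gx - x0[:, None]
    dy = gy - y0[:, None]
    g = np.exp(-(dx**2 + dy**2) * inv2s2)
    r = patches - (amp[:, None] * g + bg[:, None])
    dof = max(patches.shape[1] - 4, 1)
    resid_sd = np.sqrt((r**2).sum(axis=1) / dof)
    return ix + x0, iy + y0, amp, bg, resid_sd


def _render_gaussians(
    shape: tuple[int, int],
    x0: np.ndarray,
    y0: np.ndarray,
    amp: np.ndarray,
    sigma: float,
) -> np.ndarray:
    img = np.zeros(shape)
    h, w = shape
    half = int(np.ceil(4.0 * sigma))
    inv2s2 = 1.0 / (2.0 * sigma**2)
    for xc, yc, a in zip(x0, y0, amp):
        ix, iy = int(round(xc)), int(round(yc))
        xlo, xhi = max(ix - half, 0), min(ix + half + 1, w)
        ylo, yhi = max(iy - half, 0), min(iy + half + 1, h)
        if xlo >= xhi or ylo >= yhi:
            continue
        xs = np.arange(xlo, xhi) - xc
        ys = np.arange(ylo, yhi) - yc
        img[ylo:yhi, xlo:xhi] += a * np.exp(
            -(xs[None, :] ** 2 + ys[:, None] ** 2) * inv2s2
        )
    return img


def _detect_pass(
    img: np.ndarray, psf_sigma: float, alpha: float, min_log_snr: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One LoG + Gaussian-fit detection pass; returns kept (x, y, A, resid)."""
    empty = (np.empty(0),) * 4
    if np.ptp(img) == 0:
        return empty
    # bright spots -> strong negative Laplacian response; negate for maxima
    log = -ndimage.gaussian_laplace(img, sigma=psf_sigma)
    neigh = ndimage.maximum_filter(log, size=3, mode="nearest")
    thresh = min_log_snr * np.ptp(log)
    cand = (log >= neigh) & (log > thresh)
    ys, xs = np.nonzero(cand)
    if xs.size == 0:
        return empty
    k = int(np.ceil(3.0 * psf_sigma))
    x0, y0, amp, _, resid_sd = _gaussian_fit_batch(
        img, np.column_stack([xs, ys]).astype(float), psf_sigma, k
    )
    # amplitude significance: A / se(A) against Student t at level alpha
    n_pix = (2 * k + 1) ** 2
    g_norm = np.pi * psf_sigma**2  # sum of g^2 for a unit Gaussian
    se_amp = resid_sd / np.sqrt(g_norm)
    tcrit = student_t.ppf(1.0 - alpha, df=n_pix - 4)
    keep = (amp > 0) & (amp / np.maximum(se_amp, 1e-12) > tcrit)
    h, w = img.shape
    keep &= (x0 >= 0) & (x0 < w) & (y0 >= 0) & (y0 < h)
    return x0[keep], y0[keep], amp[keep], resid_sd[keep]


def detect_beads(
    image: np.ndarray,
    psf_sigma: float = 1.5,
    alpha: float = 0.05,
    min_log_snr: float = 1e-3,
    deflation_rounds: int = 0,
    min_separation: float = 1.5,
) -> list[Detection]:
    """Detect and localize beads at sub-pixel precision.

    A first LoG + Gaussian-fit pass finds the resolvable emitters; at
    realistic bead densities many local maxima are blends of two or more
    beads, so ``deflation_rounds`` additional passes subtract the fitted
    Gaussians and re-detect what remains in the residual image (candidates
    closer than ``min_separation`` px to an existing detection are
    dropped).

    Parameters
    ----------
    psf_sigma : expected bead PSF standard deviation (px); also the LoG
        filter scale and the fixed width of the Gaussian fit.
    alpha : significance level of the amplitude t-test against local
        residual noise.

    Returns an empty list for a flat image.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    img = np.asarray(image, dtype=float)
    x0, y0, amp, resid = _detect_pass(img, psf_sigma, alpha, min_log_snr)
    for _ in range(deflation_rounds):
        if x0.size == 0:
            break
        residual = img - _render_gaussians(img.shape, x0, y0, amp, psf_sigma)
        nx, ny, namp, nres = _detect_pass(residual, psf_sigma, alpha, min_log_snr)
        if nx.size == 0:
            break
        from scipy.spatial import cKDTree

        d, _ = cKDTree(np.column_stack([x0, y0])).query(np.column_stack([nx, ny]))
        sel = d >= min_separation
        if not sel.any():
            break
        x0 = np.concatenate([x0, nx[sel]])
        y0 = np.concatenate([y0, ny[sel]])
        amp = np.concatenate([amp, namp[sel]])
        resid = np.concatenate([resid, nres[sel]])
    return [
        Detection(
            position=(float(x0[i]), float(y0[i])),
            amplitude=float(amp[i]),
            fit_residual=float(resid[i]),
            sigma_fit=psf_sigma,
        )
        for i in range(x0.size)
    ]


def detections_to_array(detections: list[Detection]) -> np.ndarray:
    """(n, 2) array of detection positions."""
    if not detections:
        return np.empty((0, 2))
    return np.array([d.position for d in detections])
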