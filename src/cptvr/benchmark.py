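"""Synthetic bead-image benchmark with a known traction and displacement field.

The benchmark emulates a traction force microscopy (TFM) experiment on a
linear-elastic half-space: a designed surface traction field (one large
focal-adhesion-like spot plus several small spots) deforms a gel whose
surface is decorated with fluorescent beads.  The surface displacement is
obtained by integrating the Boussinesq Green's function for tangential
point loads over the traction distribution, each bead center is advected
by the displacement evaluated at its own position, and both configurations
are rendered as diffraction-limited Gaussian spot images.

Conventions
-----------
* x = column, y = row, origin at the top-left pixel center, 0-based.
* Positions and displacements are in pixels.  Because the half-space
  Green's function scales as 1/(E r), the displacement expressed in pixels
  is independent of the physical pixel size; ``pixel_size`` (nm/px) is
  carried only for physical-unit conversion.
* Tractions are in Pa, Young's modulus in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ElasticHalfSpace",
    "ForceSpot",
    "TractionField",
    "BeadField",
    "BenchmarkConfig",
    "Benchmark",
    "make_traction_field",
    "boussinesq_displacement",
    "sample_beads",
    "deform_beads",
    "render_image",
    "make_benchmark",
    "default_spots",
]


@dataclass(frozen=True)
class ElasticHalfSpace:
    """Isotropic linear-elastic half-space (the gel substrate)."""

    E: float  # Young's modulus, Pa
    nu: float = 0.5  # Poisson's ratio; 0.5 = incompressible silicone/PAA gel

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"Young's modulus must be positive, got E={self.E}")
        if not 0.0 <= self.nu <= 0.5:
            raise ValueError(f"Poisson's ratio must be in [0, 0.5], got nu={self.nu}")


@dataclass(frozen=True)
class ForceSpot:
    """One elliptical traction spot (a focal-adhesion-scale force patch).

    ``orientation`` is both the direction of the traction vector and the
    direction of the ellipse major axis (adhesions elongate along the
    force they transmit).  For the Gaussian profile the radii are the
    standard deviations along the major/minor axes; for the uniform
    profile they are hard semi-axes.
    """

    center: tuple[float, float]  # (x, y), px
    peak_magnitude: float  # Pa
    orientation: float  # rad
    radius_major: float  # px
    radius_minor: float  # px
    profile: Literal["gaussian", "uniform"] = "gaussian"

    def __post_init__(self) -> None:
        if self.peak_magnitude < 0:
            raise ValueError("peak_magnitude must be >= 0")
        if self.radius_major <= 0 or self.radius_minor <= 0:
            raise ValueError("spot radii must be > 0")


@dataclass
class TractionField:
    """Tangential surface stress (Pa) sampled on a regular pixel grid."""

    tx: np.ndarray  # (H, W), Pa
    ty: np.ndarray  # (H, W), Pa
    pixel_size: float = 108.0  # nm per pixel

    def __post_init__(self) -> None:
        self.tx = np.asarray(self.tx, dtype=float)
        self.ty = np.asarray(self.ty, dtype=float)
        if self.tx.shape != self.ty.shape:
            raise ValueError("tx and ty must have the same shape")
        if not (np.isfinite(self.tx).all() and np.isfinite(self.ty).all()):
            raise ValueError("traction components must be finite everywhere")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.tx.shape

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)


@dataclass
class BeadField:
    """Sub-pixel bead centers with per-bead amplitudes and a common PSF width."""

    positions: np.ndarray  # (n, 2) of (x, y), px
    amplitudes: np.ndarray  # (n,), intensity units
    sigma: float = 1.5  # PSF standard deviation, px
    seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if self.amplitudes.shape[0] != self.positions.shape[0]:
            raise ValueError("amplitudes must match positions")
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be > 0")

    def __len__(self) -> int:
        return self.positions.shape[0]


def make_traction_field(
    spots: Sequence[ForceSpot],
    grid_shape: tuple[int, int],
    pixel_size: float = 108.0,
    support_sigmas: float = 4.5,
) -> TractionField:
    """Superpose elliptical traction spots on a regular grid.

    Gaussian profiles are truncated to exact zero beyond ``support_sigmas``
    standard deviations so the field has compact support (this keeps the
    forward integration over nonzero cells cheap and makes "far from all
    spots" exactly traction-free).
    """
    if len(spots) == 0:
        raise ValueError("at least one ForceSpot is required")
    h, w = int(grid_shape[0]), int(grid_shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("grid_shape must be positive")
    tx = np.zeros((h, w))
    ty = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for spot in spots:
        cx, cy = spot.center
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError(f"spot center {spot.center} outside grid {grid_shape}")
        ct, st = np.cos(spot.orientation), np.sin(spot.orientation)
        # coordinates in the spot frame (major axis along orientation)
        dx = xx - cx
        dy = yy - cy
        xm = dx * ct + dy * st
        ym = -dx * st + dy * ct
        if spot.profile == "gaussian":
            q = (xm / spot.radius_major) ** 2 + (ym / spot.radius_minor) ** 2
            prof = np.where(q <= support_sigmas**2, np.exp(-0.5 * q), 0.0)
        elif spot.profile == "uniform":
            q = (xm / spot.radius_major) ** 2 + (ym / spot.radius_minor) ** 2
            prof = (q <= 1.0).astype(float)
        else:
            raise ValueError(f"unknown profile {spot.profile!r}")
        tx += spot.peak_magnitude * ct * prof
        ty += spot.peak_magnitude * st * prof
    return TractionField(tx=tx, ty=ty, pixel_size=pixel_size)


def _rect_greens_integrals(
    x1: np.ndarray, x2: np.ndarray, y1: np.ndarray, y2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Analytic integrals of 1/r, x^2/r^3, y^2/r^3, xy/r^3 over rectangles.

    The rectangle [x1, x2] x [y1, y2] is expressed relative to the
    evaluation point.  Antiderivatives (finite even when the rectangle
    contains the origin):

        F_1  = y ln(x + r) + x ln(y + r)
        F_xx = y ln(x + r)
        F_yy = x ln(y + r)
        F_xy = -r
    """

    def corner(fx, fy):
        # alternating-sign corner sum F(x2,y2) - F(x1,y2) - F(x2,y1) + F(x1,y1)
        return (
            fx(x2, y2) - fx(x1, y2) - fx(x2, y1) + fx(x1, y1)
            if fy is None
            else fx(x2, y2) - fx(x1, y2) - fx(x2, y1) + fx(x1, y1)
        )

    def ylogxr(x, y):
        r = np.hypot(x, y)
        # y * ln(x + r): the log argument vanishes only for y == 0, x <= 0
        # where the prefactor is zero as well.
        arg = x + r
        safe = np.where(arg > 0, arg, 1.0)
        return np.where(y != 0, y * np.log(safe), 0.0)

    def xlogyr(x, y):
        return ylogxr(y, x)

    def negr(x, y):
        return -np.hypot(x, y)

    i_xx = corner(ylogxr, None)
    i_yy = corner(xlogyr, None)
    i_one = i_xx + i_yy
    i_xy = corner(negr, None)
    return i_one, i_xx, i_yy, i_xy


def boussinesq_displacement(
    traction: TractionField,
    material: ElasticHalfSpace,
    eval_points: np.ndarray,
    near_radius: float = 10.0,
    chunk: int = 128,
) -> np.ndarray:
    """Surface displacement (px) from a gridded traction field.

    Integrates the Boussinesq half-space Green's function for tangential
    surface loads,

        G(s) = (1+nu) / (pi E r^3) [[(1-nu) r^2 + nu s_x^2,  nu s_x s_y],
                                    [nu s_x s_y,  (1-nu) r^2 + nu s_y^2]],

    over every nonzero traction cell (constant traction per cell).  Cells
    farther than ``near_radius`` from the evaluation point use midpoint
    quadrature; nearby cells — including the singular self-cell — use the
    exact analytic rectangle integral, so the result is finite everywhere
    and converges under grid refinement.

    Parameters
    ----------
    eval_points : (n, 2) array of (x, y) pixel positions.

    Returns
    -------
    (n, 2) array of (u, v) displacements in pixels.
    """
    pts = np.atleast_2d(np.asarray(eval_points, dtype=float))
    n = pts.shape[0]
    out = np.zeros((n, 2))
    mag = traction.magnitude
    rows, cols = np.nonzero(mag)
    if rows.size == 0 or n == 0:
        return out
    cx = cols.astype(float)
    cy = rows.astype(float)
    tx = traction.tx[rows, cols]
    ty = traction.ty[rows, cols]
    nu = material.nu
    c = (1.0 + nu) / (np.pi * material.E)

    # --- far field: midpoint quadrature, chunked over evaluation points
    for i0 in range(0, n, chunk):
        p = pts[i0 : i0 + chunk]
        dx = p[:, 0:1] - cx[None, :]
        dy = p[:, 1:2] - cy[None, :]
        r2 = dx * dx + dy * dy
        # inclusive bound to match the KD-tree near query exactly (cells on
        # integer grids can sit at exactly the cutoff distance)
        near = r2 <= near_radius * near_radius * (1 + 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_r = 1.0 / np.sqrt(r2)
            inv_r3 = inv_r / r2
        inv_r[near] = 0.0
        inv_r3[near] = 0.0
        gxx = (1.0 - nu) * inv_r + nu * dx * dx * inv_r3
        gyy = (1.0 - nu) * inv_r + nu * dy * dy * inv_r3
        gxy = nu * dx * dy * inv_r3
        out[i0 : i0 + chunk, 0] = c * (gxx @ tx + gxy @ ty)
        out[i0 : i0 + chunk, 1] = c * (gxy @ tx + gyy @ ty)

    # --- near field: exact analytic integral over each nearby cell
    tree = cKDTree(np.column_stack([cx, cy]))
    pairs = tree.query_ball_point(pts, r=near_radius, return_sorted=False)
    pi_idx = np.concatenate(
        [np.full(len(cells), i) for i, cells in enumerate(pairs)]
    ) if any(len(cl) for cl in pairs) else np.empty(0, dtype=int)
    if pi_idx.size:
        ci_idx = np.concatenate([np.asarray(cl, dtype=int) for cl in pairs if len(cl)])
        ex = pts[pi_idx, 0]
        ey = pts[pi_idx, 1]
        x1 = cx[ci_idx] - 0.5 - ex
        x2 = cx[ci_idx] + 0.5 - ex
        y1 = cy[ci_idx] - 0.5 - ey
        y2 = cy[ci_idx] + 0.5 - ey
        i_one, i_xx, i_yy, i_xy = _rect_greens_integrals(x1, x2, y1, y2)
        gxx = (1.0 - nu) * i_one + nu * i_xx
        gyy = (1.0 - nu) * i_one + nu * i_yy
        gxy = nu * i_xy
        du = c * (gxx * tx[ci_idx] + gxy * ty[ci_idx])
        dv = c * (gxy * tx[ci_idx] + gyy * ty[ci_idx])
        np.add.at(out[:, 0], pi_idx, du)
        np.add.at(out[:, 1], pi_idx, dv)
    return out


def sample_beads(
    n: int,
    shape: tuple[int, int],
    seed: int | None = None,
    sigma: float = 1.5,
    amplitude_range: tuple[float, float] = (200.0, 1000.0),
) -> BeadField:
    """Draw ``n`` bead centers uniformly at random over the field of view."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    xy = np.column_stack([rng.uniform(0, w, size=n), rng.uniform(0, h, size=n)])
    amps = rng.uniform(*amplitude_range, size=n)
    return BeadField(positions=xy, amplitudes=amps, sigma=sigma, seed=seed)


def deform_beads(
    beads: BeadField, traction: TractionField, material: ElasticHalfSpace
) -> BeadField:
    """Advect each bead by the forward displacement at its own center."""
    disp = boussinesq_displacement(traction, material, beads.positions)
    return replace(beads, positions=beads.positions + disp)


def render_image(
    beads: BeadField,
    shape: tuple[int, int],
    background: float = 0.0,
    noise: Literal["none", "poisson-gaussian"] = "none",
    read_noise_sd: float = 2.0,
    rng: np.random.Generator | None = None,
    support_sigmas: float = 4.0,
) -> np.ndarray:
    """Render a bead field as a sum of isotropic 2D Gaussians.

    Each bead contributes ``A exp(-((x-x0)^2+(y-y0)^2) / (2 sigma^2))``
    rendered over a +/- ``support_sigmas``-sigma patch.  Noiseless
    rendering is fully deterministic.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    img = np.full((h, w), float(background))
    if len(beads):
        half = int(np.ceil(support_sigmas * beads.sigma))
        inv2s2 = 1.0 / (2.0 * beads.sigma**2)
        for (x0, y0), a in zip(beads.positions, beads.amplitudes):
            ix, iy = int(round(x0)), int(round(y0))
            xlo, xhi = max(ix - half, 0), min(ix + half + 1, w)
            ylo, yhi = max(iy - half, 0), min(iy + half + 1, h)
            if xlo >= xhi or ylo >= yhi:
                continue
            xs = np.arange(xlo, xhi) - x0
            ys = np.arange(ylo, yhi) - y0
            img[ylo:yhi, xlo:xhi] += a * np.exp(
                -(xs[None, :] ** 2 + ys[:, None] ** 2) * inv2s2
            )
    if noise == "poisson-gaussian":
        rng = np.random.default_rng() if rng is None else rng
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
        img += rng.normal(0.0, read_noise_sd, size=img.shape)
        img = np.clip(img, 0.0, None)
    elif noise != "none":
        raise ValueError(f"unknown noise model {noise!r}")
    return img


def default_spots() -> list[ForceSpot]:
    """Canonical spot layout: one large central ~12 kPa adhesion-scale spot
    plus six small peripheral spots (250-500 Pa)."""
    large = ForceSpot(
        center=(256.0, 256.0),
        peak_magnitude=12000.0,
        orientation=np.deg2rad(35.0),
        radius_major=15.0,
        radius_minor=10.0,
    )
    small = [
        ForceSpot((110.0, 100.0), 500.0, np.deg2rad(210.0), 8.0, 5.0),
        ForceSpot((150.0, 395.0), 400.0, np.deg2rad(120.0), 7.0, 5.0),
        ForceSpot((395.0, 120.0), 450.0, np.deg2rad(300.0), 8.0, 5.0),
        ForceSpot((400.0, 385.0), 350.0, np.deg2rad(45.0), 7.0, 4.0),
        ForceSpot((70.0, 255.0), 300.0, np.deg2rad(170.0), 6.0, 4.0),
        ForceSpot((430.0, 260.0), 250.0, np.deg2rad(0.0), 6.0, 4.0),
    ]
    return [large] + small


@dataclass
class BenchmarkConfig:
    """Study conditions for the synthetic benchmark (defaults reproduce the
    standard simulation: 8000 beads on 512x512 px, E = 8 kPa, nu = 0.5)."""

    n_beads: int = 8000
    shape: tuple[int, int] = (512, 512)
    spots: list[ForceSpot] = field(default_factory=default_spots)
    E: float = 8000.0  # Pa
    nu: float = 0.5
    pixel_size: float = 108.0  # nm/px
    bead_sigma: float = 1.5  # px
    amplitude_range: tuple[float, float] = (200.0, 1000.0)
    background: float = 100.0
    noise: Literal["none", "poisson-gaussian"] = "none"
    seed: int = 0

    @property
    def material(self) -> ElasticHalfSpace:
        return ElasticHalfSpace(E=self.E, nu=self.nu)


@dataclass
class Benchmark:
    """A complete seeded benchmark fixture."""

    config: BenchmarkConfig
    ref_image: np.ndarray
    def_image: np.ndarray
    beads_ref: BeadField
    beads_def: BeadField
    truth_displacement: np.ndarray  # (n, 2) at beads_ref.positions
    traction: TractionField
    regions: dict[str, np.ndarray]  # boolean masks: whole_field/large_force/small_force

    def truth_at(self, points: np.ndarray) -> np.ndarray:
        """Analytic ground-truth displacement at arbitrary points."""
        return boussinesq_displacement(
            self.traction, self.config.material, points
        )


def make_benchmark(config: BenchmarkConfig | None = None) -> Benchmark:
    """Generate the full benchmark: image pair, ground truth and region masks."""
    from .metrics import region_masks_displacement  # local import, avoids a cycle

    cfg = config if config is not None else BenchmarkConfig()
    traction = make_traction_field(cfg.spots, cfg.shape, cfg.pixel_size)
    beads = sample_beads(
        cfg.n_beads,
        cfg.shape,
        seed=cfg.seed,
        sigma=cfg.bead_sigma,
        amplitude_range=cfg.amplitude_range,
    )
    disp = boussinesq_displacement(traction, cfg.material, beads.positions)
    beads_def = replace(beads, positions=beads.positions + disp)
    rng = np.random.default_rng(None if cfg.seed is None else cfg.seed + 1)
    ref = render_image(beads, cfg.shape, cfg.background, cfg.noise, rng=rng)
    def_ = render_image(beads_def, cfg.shape, cfg.background, cfg.noise, rng=rng)
    regions = region_masks_displacement(cfg.spots, cfg.shape, cfg.material)
    return Benchmark(
        config=cfg,
        ref_image=ref,
        def_image=def_,
        beads_ref=beads,
        beads_def=beads_def,
        truth_displacement=disp,
        traction=traction,
        regions=regions,
    )
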