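"""Quantitative comparison of measured vs ground-truth vector fields.

Two scalar metrics are computed over a chosen region of interest:

* deviation ratio, historically called "mean squared deviation" (MSD):

      MSD = sum_i |V_g,i - V_m,i| / sum_i |V_g,i|

  Note: despite the name, the formula is an L1-normalized deviation (no
  squaring); it is implemented exactly as defined.

* accuracy:

      Acc = (1/N) sum_i ( 1 - |V_g,i - V_m,i| / mean(|V_g|) )

  Acc = 1 means every ground-truth vector is tracked exactly; missed or
  wrong vectors lower it, and a single badly missed large vector can
  drive individual terms negative.

``V_g`` is the ground-truth displacement evaluated at the *measured*
vector origins (analytically through the forward model when available).
Vectors with status 'failed' or 'filtered' enter either as zero
displacement (``missing_policy='zero'``, the default — a miss is an
error) or are excluded (``missing_policy='exclude'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.morphology import disk

from .benchmark import Benchmark, TractionField, boussinesq_displacement
from .tracking import DisplacementField

__all__ = [
    "MetricResult",
    "evaluate_truth_at",
    "field_metrics",
    "msd",
    "accuracy",
    "region_masks",
    "region_masks_displacement",
    "points_in_region",
]


@dataclass
class MetricResult:
    msd: float
    accuracy: float
    n_vectors: int
    region: str = "whole_field"
    missing_policy: str = "zero"


def evaluate_truth_at(benchmark: Benchmark, origins: np.ndarray) -> np.ndarray:
    """Analytic ground-truth displacement at each measured origin."""
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    if origins.shape[0] == 0:
        return np.empty((0, 2))
    h, w = benchmark.config.shape
    inside = (
        (origins[:, 0] >= 0)
        & (origins[:, 0] < w)
        & (origins[:, 1] >= 0)
        & (origins[:, 1] < h)
    )
    if not inside.all():
        import warnings

        warnings.warn(
            f"{int((~inside).sum())} origins outside the field of view "
            "were assigned zero truth",
            stacklevel=2,
        )
    out = np.zeros((origins.shape[0], 2))
    out[inside] = boussinesq_displacement(
        benchmark.traction, benchmark.config.material, origins[inside]
    )
    return out


def _prepare(
    measured: DisplacementField,
    truth: np.ndarray,
    region: np.ndarray | None,
    missing_policy: str,
) -> tuple[np.ndarray, np.ndarray]:
    truth = np.asarray(truth, dtype=float)
    if truth.shape != (len(measured), 2):
        raise ValueError("truth must be (n, 2) matching the measured field")
    if missing_policy not in ("zero", "exclude"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    sel = np.ones(len(measured), dtype=bool)
    if region is not None:
        sel &= points_in_region(measured.origins, region)
    vm = measured.vectors.copy()
    conf = measured.confident_mask()
    if missing_policy == "zero":
        vm[~conf] = 0.0
    else:
        sel &= conf
    return vm[sel], truth[sel]


def field_metrics(
    measured: DisplacementField,
    truth: np.ndarray,
    region: np.ndarray | None = None,
    missing_policy: str = "zero",
    region_label: str = "whole_field",
) -> MetricResult:
    """Deviation ratio (Eq. MSD) and accuracy over one region."""
    vm, vg = _prepare(measured, truth, region, missing_policy)
    n = vm.shape[0]
    if n == 0:
        raise ValueError("no vectors in the requested region")
    dev = np.hypot(vm[:, 0] - vg[:, 0], vm[:, 1] - vg[:, 1])
    gmag = np.hypot(vg[:, 0], vg[:, 1])
    denom = gmag.sum()
    if denom == 0:
        raise ValueError("ground truth is identically zero in the region; "
                         "the deviation ratio is undefined")
    msd_val = float(dev.sum() / denom)
    acc_val = float(np.mean(1.0 - dev / gmag.mean()))
    return MetricResult(
        msd=msd_val,
        accuracy=acc_val,
        n_vectors=n,
        region=region_label,
        missing_policy=missing_policy,
    )


def msd(
    measured: DisplacementField,
    truth: np.ndarray,
    region: np.ndarray | None = None,
    missing_policy: str = "zero",
    region_label: str = "whole_field",
) -> MetricResult:
    return field_metrics(measured, truth, region, missing_policy, region_label)


def accuracy(
    measured: DisplacementField,
    truth: np.ndarray,
    region: np.ndarray | None = None,
    missing_policy: str = "zero",
    region_label: str = "whole_field",
) -> MetricResult:
    return field_metrics(measured, truth, region, missing_policy, region_label)


def points_in_region(points: np.ndarray, region: np.ndarray) -> np.ndarray:
    """Boolean membership of sub-pixel points in a pixel mask."""
    pts = np.atleast_2d(points)
    h, w = region.shape
    ix = np.clip(np.round(pts[:, 0]).astype(int), 0, w - 1)
    iy = np.clip(np.round(pts[:, 1]).astype(int), 0, h - 1)
    inside = (
        (pts[:, 0] >= -0.5)
        & (pts[:, 0] < w - 0.5)
        & (pts[:, 1] >= -0.5)
        & (pts[:, 1] < h - 0.5)
    )
    return inside & region[iy, ix]


def region_masks_displacement(
    spots,
    grid_shape: tuple[int, int],
    material,
    frac: float = 0.1,
    large_peak_threshold: float = 1000.0,
    stride: int = 4,
) -> dict[str, np.ndarray]:
    """Region masks from the *displacement* footprint of each force group.

    The regions of interest are defined on the ground-truth displacement
    map: the large-force region is where the displacement produced by
    the large spot(s) alone exceeds ``frac`` of its own peak (the
    visible extent of the displacement blob), and likewise for the small
    spots, with the large region taking precedence so the two stay
    disjoint.  Because the half-space response decays like 1/r, these
    regions extend well beyond the traction support itself.

    Spots with peak magnitude above ``large_peak_threshold`` (Pa) form
    the "large force" group.  The forward solution is evaluated on a
    ``stride``-subsampled grid and upsampled, which is ample for a mask.
    """
    from .benchmark import boussinesq_displacement, make_traction_field

    if frac <= 0 or frac >= 1:
        raise ValueError("frac must be in (0, 1)")
    large_spots = [s for s in spots if s.peak_magnitude >= large_peak_threshold]
    small_spots = [s for s in spots if s.peak_magnitude < large_peak_threshold]
    h, w = grid_shape
    gh, gw = h // stride, w // stride
    ys, xs = np.mgrid[0:gh, 0:gw]
    pts = np.column_stack(
        [xs.ravel() * stride + (stride - 1) / 2, ys.ravel() * stride + (stride - 1) / 2]
    ).astype(float)

    def footprint(group):
        if not group:
            return np.zeros((gh, gw), dtype=bool)
        tf = make_traction_field(group, grid_shape)
        u = boussinesq_displacement(tf, material, pts)
        mag = np.hypot(u[:, 0], u[:, 1]).reshape(gh, gw)
        return mag >= frac * mag.max()

    large = footprint(large_spots)
    small = footprint(small_spots) & ~large
    up = np.ones((stride, stride), dtype=bool)
    large_full = np.kron(large, up)
    small_full = np.kron(small, up)
    whole = np.ones(grid_shape, dtype=bool)
    return {
        "whole_field": whole,
        "large_force": large_full,
        "small_force": small_full,
    }


def region_masks(
    truth_traction: TractionField,
    large_threshold: float = 1000.0,
    small_threshold: float = 50.0,
    dilation_px: int = 10,
) -> dict[str, np.ndarray]:
    """Region-of-interest masks derived from the traction support.

    ``large_force`` is the dilated support of traction above
    ``large_threshold`` (the central adhesion-scale spot);
    ``small_force`` is the dilated support of the remaining spots above
    ``small_threshold``, minus the large region.  The two are disjoint by
    construction.  Note that the canonical benchmark uses
    :func:`region_masks_displacement` instead — the comparison regions
    are drawn on the displacement map, not the traction map.
    """
    if not 0 < small_threshold < large_threshold:
        raise ValueError(
            "thresholds must satisfy 0 < small_threshold < large_threshold"
        )
    mag = truth_traction.magnitude
    selem = disk(dilation_px)
    large = binary_dilation(mag > large_threshold, structure=selem)
    small_support = (mag > small_threshold) & ~large
    small = binary_dilation(small_support, structure=selem) & ~large
    whole = np.ones_like(large, dtype=bool)
    return {"whole_field": whole, "large_force": large, "small_force": small}
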