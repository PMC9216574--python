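"""Correlation-based particle tracking velocimetry (cPTV).

Each detected bead seeds an interrogation: a template window from the
reference image is swept over the deformed image within a bounded shift
range and scored with the zero-normalized cross-correlation

    S(ux, uy) = sum (I_ref - mean) (I_def - mean)
                / sqrt( sum (I_ref - mean)^2  sum (I_def - mean)^2 ),

where the means are taken over the template and over the shifted window
respectively.  The global score maximum is accepted only if it clearly
dominates the secondary local maximum (peak-ratio significance test), and
accepted shifts are refined to sub-pixel precision by fitting a quadratic
surface to the 3x3 score neighborhood.  Vector outliers are removed with
a normalized vector-median test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter
from scipy.spatial import cKDTree
from skimage.feature import match_template

__all__ = [
    "ScoreMap",
    "TemplateSpec",
    "TrackConfig",
    "DisplacementField",
    "ncc_score_map",
    "find_local_maxima",
    "significance_test",
    "subpixel_refine",
    "track_cptv",
    "vector_median_filter",
    "STATUS_TRACKED",
    "STATUS_FAILED",
    "STATUS_FILTERED",
    "STATUS_RETRACKED",
]

STATUS_TRACKED = "tracked"
STATUS_FAILED = "failed"
STATUS_FILTERED = "filtered"
STATUS_RETRACKED = "retracked"
CONFIDENT_STATUSES = (STATUS_TRACKED, STATUS_RETRACKED)


@dataclass(frozen=True)
class TemplateSpec:
    """Interrogation template: half-length L (window = 2L+1 px) centered on
    a sub-pixel bead position (the window itself is pixel-aligned)."""

    half_length: int
    center: tuple[float, float]  # (x, y), px

    def __post_init__(self) -> None:
        if self.half_length < 3:
            raise ValueError("template half-length must be >= 3")


@dataclass
class ScoreMap:
    """NCC scores over integer shifts (ux, uy) in [-u_max, u_max]^2.

    ``scores[u_max + uy, u_max + ux]`` is the score at shift (ux, uy);
    shifts whose search window falls outside the deformed image are NaN.
    ``mask`` (optional) marks admissible shifts; inadmissible or undefined
    shifts are ignored by peak finding.
    """

    scores: np.ndarray
    u_max: int
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = 2 * self.u_max + 1
        if self.scores.shape != (n, n):
            raise ValueError("scores shape must be (2*u_max+1, 2*u_max+1)")
        if self.mask is not None and self.mask.shape != self.scores.shape:
            raise ValueError("mask must have the same shape as scores")

    def valid(self) -> np.ndarray:
        v = np.isfinite(self.scores)
        if self.mask is not None:
            v &= self.mask
        return v

    def shift_of(self, index: tuple[int, int]) -> tuple[int, int]:
        iy, ix = index
        return ix - self.u_max, iy - self.u_max


@dataclass
class TrackConfig:
    """Parameters of the initial cPTV pass."""

    half_length: int = 10  # template window = 21 px
    u_max: int = 29  # search extent per axis (< 30 px)
    significance: float = 0.65  # strict peak-ratio criterion
    significance_mode: str = "second"  # or "all"
    filter_radius: float = 15.0  # px, vector-median neighborhood
    filter_threshold: float = 2.0  # normalized-residual cutoff
    filter_eps: float = 0.1  # px, residual normalization floor


@dataclass
class DisplacementField:
    """Sparse displacement vectors, one per interrogated bead.

    ``u``/``v`` are NaN wherever ``status`` is 'failed'; 'filtered'
    vectors keep their (rejected) values but are excluded from the
    confident set used by retracking and interpolation.
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    score: np.ndarray
    status: np.ndarray  # str array
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "u", "v", "score", "status"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def origins(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def vectors(self) -> np.ndarray:
        return np.column_stack([self.u, self.v])

    def confident_mask(self) -> np.ndarray:
        return np.isin(self.status, CONFIDENT_STATUSES)

    def copy(self) -> "DisplacementField":
        return DisplacementField(
            x=self.x.copy(),
            y=self.y.copy(),
            u=self.u.copy(),
            v=self.v.copy(),
            score=self.score.copy(),
            status=self.status.copy(),
            provenance=dict(self.provenance),
        )

    def counts(self) -> dict[str, int]:
        vals, cnt = np.unique(self.status, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))


def ncc_score_map(
    ref: np.ndarray,
    def_: np.ndarray,
    template: TemplateSpec,
    u_max: int,
) -> ScoreMap | None:
    """Zero-normalized cross-correlation score map for one bead.

    Returns None when the template has zero variance (flat patch) or the
    bead sits too close to the border for a minimal window.  The
    correlation itself is evaluated in the frequency domain
    (:func:`skimage.feature.match_template`), which agrees with the direct
    double-sum definition to floating-point precision.
    """
    h, w = ref.shape
    cx = int(round(template.center[0]))
    cy = int(round(template.center[1]))
    # clamp the half-length so the template fits inside the reference image
    L = min(template.half_length, cx, cy, w - 1 - cx, h - 1 - cy)
    if L < 3:
        return None
    tpl = ref[cy - L : cy + L + 1, cx - L : cx + L + 1]
    if np.ptp(tpl) == 0:
        return None
    # search region in the deformed image, clipped at borders
    ry0 = max(cy - L - u_max, 0)
    ry1 = min(cy + L + u_max + 1, h)
    rx0 = max(cx - L - u_max, 0)
    rx1 = min(cx + L + u_max + 1, w)
    region = def_[ry0:ry1, rx0:rx1]
    if region.shape[0] < 2 * L + 1 or region.shape[1] < 2 * L + 1:
        return None
    res = match_template(region, tpl, pad_input=False)
    n = 2 * u_max + 1
    scores = np.full((n, n), np.nan)
    # map result index (i, j) -> shift (rx0 + j - (cx - L), ry0 + i - (cy - L))
    uy0 = ry0 - (cy - L)
    ux0 = rx0 - (cx - L)
    scores[
        u_max + uy0 : u_max + uy0 + res.shape[0],
        u_max + ux0 : u_max + ux0 + res.shape[1],
    ] = np.clip(res, -1.0, 1.0)
    return ScoreMap(scores=scores, u_max=u_max)


def find_local_maxima(smap: ScoreMap) -> list[tuple[float, tuple[int, int]]]:
    """Strict 8-neighborhood local maxima of the (masked) score map.

    Returns ``[(score, (ux, uy)), ...]`` sorted by descending score; ties
    broken toward smaller shift magnitude, then lexicographically.
    """
    s = np.where(smap.valid(), smap.scores, -np.inf)
    if not np.isfinite(s).any():
        return []
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neigh_max = maximum_filter(s, footprint=footprint, mode="constant", cval=-np.inf)
    peak = np.isfinite(s) & (s > neigh_max)
    iy, ix = np.nonzero(peak)
    if iy.size == 0:
        return []
    ux = ix - smap.u_max
    uy = iy - smap.u_max
    sc = s[iy, ix]
    order = np.lexsort((uy, ux, ux**2 + uy**2, -sc))
    return [(float(sc[k]), (int(ux[k]), int(uy[k]))) for k in order]


def significance_test(
    peaks: Sequence[tuple[float, tuple[int, int]]],
    ratio_threshold: float,
    mode: str = "second",
) -> bool:
    """Peak-ratio significance criterion.

    The global maximum is trusted iff the secondary local maximum (or, in
    ``mode='all'``, every non-global maximum) is at most
    ``ratio_threshold`` times its score.  A higher threshold is more
    generous (admits more vectors); a lower one is stricter.
    """
    if len(peaks) == 0:
        return False
    top = peaks[0][0]
    if top <= 0:
        return False
    if len(peaks) == 1:
        return True
    others = [p[0] for p in peaks[1:]] if mode == "all" else [peaks[1][0]]
    return all(s / top <= ratio_threshold for s in others)


def subpixel_refine(
    smap: ScoreMap, peak: tuple[int, int]
) -> tuple[float, float, bool]:
    """Refine an integer peak by fitting a quadratic surface to its 3x3
    score neighborhood; the offset is clamped to +/- 0.5 px per axis.

    Returns (u, v, refined); ``refined`` is False when the peak touches
    the map border (or undefined scores) and the integer shift is
    returned unchanged.
    """
    ux, uy = peak
    R = smap.u_max
    ix, iy = ux + R, uy + R
    n = 2 * R + 1
    if not (0 < ix < n - 1 and 0 < iy < n - 1):
        return float(ux), float(uy), False
    patch = smap.scores[iy - 1 : iy + 2, ix - 1 : ix + 2]
    if smap.mask is not None:
        # inadmissible neighbors still carry genuine correlation scores;
        # use them for the surface fit when they are defined
        pass
    if not np.isfinite(patch).all():
        return float(ux), float(uy), False
    gy, gx = np.mgrid[-1:2, -1:2].astype(float)
    A = np.column_stack(
        [
            np.ones(9),
            gx.ravel(),
            gy.ravel(),
            gx.ravel() ** 2,
            gx.ravel() * gy.ravel(),
            gy.ravel() ** 2,
        ]
    )
    coef, *_ = np.linalg.lstsq(A, patch.ravel(), rcond=None)
    _, b, c, d, e, f = coef
    hess = np.array([[2 * d, e], [e, 2 * f]])
    det = np.linalg.det(hess)
    if det <= 0 or hess[0, 0] >= 0:  # not a maximum
        return float(ux), float(uy), False
    off = np.linalg.solve(hess, [-b, -c])
    clamped = bool(np.any(np.abs(off) > 0.5))
    off = np.clip(off, -0.5, 0.5)
    return float(ux + off[0]), float(uy + off[1]), not clamped


def _interrogate(
    ref: np.ndarray,
    def_: np.ndarray,
    center: tuple[float, float],
    half_length: int,
    u_max: int,
    significance: float,
    mode: str,
) -> tuple[float, float, float] | None:
    """One full interrogation; returns (u, v, score) or None on failure."""
    smap = ncc_score_map(ref, def_, TemplateSpec(half_length, center), u_max)
    if smap is None:
        return None
    peaks = find_local_maxima(smap)
    if not peaks or not significance_test(peaks, significance, mode):
        return None
    score, ipeak = peaks[0]
    u, v, _ = subpixel_refine(smap, ipeak)
    return u, v, score


def track_cptv(
    ref: np.ndarray,
    def_: np.ndarray,
    detections: np.ndarray,
    config: TrackConfig | None = None,
) -> DisplacementField:
    """Track every detected bead; per-bead failures are recorded, not raised."""
    cfg = config if config is not None else TrackConfig()
    pts = np.atleast_2d(np.asarray(detections, dtype=float))
    n = pts.shape[0]
    if n == 0:
        raise ValueError("detections must be non-empty")
    u = np.full(n, np.nan)
    v = np.full(n, np.nan)
    score = np.full(n, np.nan)
    status = np.full(n, STATUS_FAILED, dtype=object)
    for i in range(n):
        res = _interrogate(
            ref,
            def_,
            (pts[i, 0], pts[i, 1]),
            cfg.half_length,
            cfg.u_max,
            cfg.significance,
            cfg.significance_mode,
        )
        if res is not None:
            u[i], v[i], score[i] = res
            status[i] = STATUS_TRACKED
    return DisplacementField(
        x=pts[:, 0].copy(),
        y=pts[:, 1].copy(),
        u=u,
        v=v,
        score=score,
        status=status,
        provenance={"tracker": "cptv", "config": vars(cfg).copy()},
    )


def vector_median_filter(
    field_in: DisplacementField,
    radius: float | None = None,
    threshold: float | None = None,
    eps: float | None = None,
) -> DisplacementField:
    """Normalized vector-median outlier test.

    Each confident vector is compared with the component-wise median of
    its confident neighbors inside ``radius``; its residual, normalized
    by the neighborhood median absolute residual plus ``eps``, must not
    exceed ``threshold``.  Vectors without neighbors are left unchanged.
    """
    cfg = TrackConfig()
    radius = cfg.filter_radius if radius is None else radius
    threshold = cfg.filter_threshold if threshold is None else threshold
    eps = cfg.filter_eps if eps is None else eps
    if radius <= 0:
        raise ValueError("radius must be > 0")
    out = field_in.copy()
    conf = out.confident_mask()
    idx = np.nonzero(conf)[0]
    if idx.size < 2:
        return out
    pts = out.origins[idx]
    vec = out.vectors[idx]
    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, r=radius, return_sorted=False)
    flagged = []
    for k, nb in enumerate(neighbors):
        nb = [j for j in nb if j != k]
        if not nb:
            continue
        nb_vec = vec[nb]
        med = np.median(nb_vec, axis=0)
        resid = float(np.hypot(*(vec[k] - med)))
        nb_resid = np.hypot(nb_vec[:, 0] - med[0], nb_vec[:, 1] - med[1])
        norm = float(np.median(nb_resid)) + eps
        if resid / norm > threshold:
            flagged.append(idx[k])
    if flagged:
        out.status[np.asarray(flagged)] = STATUS_FILTERED
    out.provenance["median_filter"] = {
        "radius": radius,
        "threshold": threshold,
        "eps": eps,
        "n_filtered": len(flagged),
    }
    return out
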