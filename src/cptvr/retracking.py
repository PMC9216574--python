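"""Neighbor-guided retracking of failed displacement vectors (cPTVR).

Large, locally concentrated gel deformations decorrelate the bead image
so badly that the true shift is not the global cross-correlation maximum;
a plain correlation tracker therefore fails, or is filtered out, exactly
where the biggest vectors are.  Retracking rescues those locations using
the statistically confident vectors around them:

1. Seed points = vectors that failed tracking or were filtered out.
2. Per seed, confident neighbors are gathered within an adaptive search
   radius and summarized (median vector ``u_nei``, magnitude spread,
   circular angle statistics).  The median is used because neighbor
   magnitudes around a missed large vector are biased low and
   non-Gaussian.
3. The correlation map is masked to shifts whose magnitude lies in
   [0.5 |u_nei|, 3 |u_nei|] (a deliberately generous upper limit — the
   missing vector is expected to be at least as large as its neighbors)
   and whose angle lies within +/- 2 circular standard deviations of the
   neighbor mean direction.
4. If the masked global maximum passes the peak-ratio significance test
   it is accepted; otherwise the local maximum closest to the model
   vector is accepted when it lies within 2 magnitude standard deviations
   and 1 angular standard deviation of the model.
5. On failure the template window shrinks by 2 px and the search repeats,
   down to a window that holds roughly a single bead.

Each rescued vector immediately joins the confident set and guides its
still-missing neighbors, so the field fills inward from the
well-constrained rim.  An outer adaptive loop (the *enlargement factor*,
EF) multiplies the model-vector magnitude by 1.1 per escalation once
retracking stalls, favoring recovery of vectors larger than their
neighborhood median; the minimum neighbor count for the radius search is
raised first (3 -> 5 -> 8) to firm up the statistics before EF grows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .tracking import (
    STATUS_FAILED,
    STATUS_FILTERED,
    STATUS_RETRACKED,
    DisplacementField,
    ScoreMap,
    TemplateSpec,
    find_local_maxima,
    ncc_score_map,
    significance_test,
    subpixel_refine,
)

__all__ = [
    "NeighborStats",
    "RetrackConfig",
    "seed_points",
    "gather_neighbors",
    "masked_score_map",
    "select_candidate",
    "rank_candidates",
    "backward_consistent",
    "backward_match",
    "retrack_point",
    "retrack_field",
    "retrack_with_enlargement",
]


def _circular_mean_std(angles: np.ndarray) -> tuple[float, float]:
    """Circular mean and circular standard deviation of raw directions.

    Vectors pointing near +/- pi must not average to zero, hence the
    resultant-vector formulation: std = sqrt(-2 ln R)."""
    z = np.exp(1j * np.asarray(angles, dtype=float))
    mean_z = z.mean()
    r = min(max(abs(mean_z), 1e-12), 1.0)
    return float(np.angle(mean_z)), float(np.sqrt(-2.0 * np.log(r)))


def _ang_diff(a: float | np.ndarray, b: float) -> np.ndarray:
    """Absolute angular difference wrapped to [0, pi]."""
    d = (np.asarray(a, dtype=float) - b + np.pi) % (2.0 * np.pi) - np.pi
    return np.abs(d)


_POLAR_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _polar_grids(R: int) -> tuple[np.ndarray, np.ndarray]:
    """Cached (magnitude, angle) grids of the integer shift lattice."""
    if R not in _POLAR_CACHE:
        uy, ux = np.mgrid[-R : R + 1, -R : R + 1].astype(float)
        _POLAR_CACHE[R] = (np.hypot(ux, uy), np.arctan2(uy, ux))
    return _POLAR_CACHE[R]


@dataclass
class NeighborStats:
    """Summary of the confident vectors around one seed point."""

    n: int
    u_nei: np.ndarray  # component-wise median vector (2,)
    mean_vector: np.ndarray  # (2,)
    mag_std: float  # std of neighbor magnitudes, px
    mag_max: float  # largest neighbor magnitude, px
    angle_mean: float  # circular mean direction, rad
    angle_std: float  # circular std, rad
    search_radius: float  # radius that collected the neighbors, px

    @property
    def model_magnitude(self) -> float:
        return float(np.hypot(*self.u_nei))


@dataclass
class RetrackConfig:
    """Tunable parameters of the retracking stage.

    The mask and closeness constants mirror the published defaults: the
    admissible magnitude band is [0.5, 3.0] x |u_nei| (scaled by EF), the
    angular band is +/- 2 circular std, and a candidate is accepted when
    it is within ``mag_accept_k`` = 2 magnitude standard deviations and
    ``angle_accept_k`` = 1 angular standard deviation of the model vector
    (both user-adjustable)."""

    min_neighbors: int = 3
    min_neighbors_ladder: tuple[int, ...] = (3, 5, 8)
    base_half_length: int = 10  # starting template half-length (21 px window)
    window_shrink_px: int = 2  # window shrinks this much per retry
    min_window: int = 7  # px; about a single-bead window at sigma = 1.5
    u_max: int = 29  # base search extent (enlarged by the mask as needed)
    max_search: int = 80  # hard cap on the enlarged search extent, px
    significance: float = 0.65
    significance_mode: str = "second"
    mask_mag_range: tuple[float, float] = (0.5, 3.0)  # x EF |u_nei|
    mask_angle_k: float = 2.0  # x circular std
    mag_accept_k: float = 2.0  # closeness: magnitude std units
    angle_accept_k: float = 1.0  # closeness: angular std units
    angle_std_floor: float = math.radians(5.0)  # for perfectly parallel neighbors
    mag_std_floor: float = 0.5  # px, for perfectly uniform neighborhoods
    min_score: float = 0.5  # NCC floor for any retracked acceptance
    refine_snap: float = 3.0  # px; final single-bead-window re-measurement radius
    backward_check: bool = False  # reciprocal arbitration among EF candidates
    backward_policy: str = "window"  # what a veto skips: candidate|window|ef|seed
    backward_rules: tuple[str, ...] = ("closest",)  # rules subject to the veto
    mag_floor_k: float | None = 1.0  # candidate magnitude >= |u_nei| - k*mag_std
    mag_cap_k: float | None = 2.0  # candidate magnitude <= max neighbor + k*mag_std
    closest_max_half_length: int | None = 5  # closest rule only at windows <= this L
    closest_sort: str = "distance"  # candidate order: distance | score
    rule_order: str = "interleaved"  # per-window rule handling: interleaved | sig_first
    closest_window_order: str = "big"  # window ladder for the closest rule: big | small
    max_candidates: int = 4  # validated candidates tried per masked map
    backward_tol: float = 2.0  # px; allowed forward-backward disagreement
    backward_rel: float = 0.8  # near-origin backward score vs backward global
    backward_abs: float = 0.75  # absolute near-origin backward score floor
    backward_search: int = 12  # px; backward search half-extent
    initial_radius: float | None = None  # default: 2 x mean bead spacing
    radius_growth: float = 1.3
    max_radius_factor: float = 3.0  # max radius = factor x initial radius
    repair_rounds: int = 3  # revoke-and-requeue consistency passes
    repair_mode: str = "median"  # consistency model: median|affine|elastic
    repair_abs_tol: float = 3.5  # px; allowed deviation from the model prediction
    repair_lambda: float = 1e-4  # Tikhonov weight of the elastic smoother
    repair_grid: int = 64  # inversion grid of the elastic smoother
    repair_radius: float = 15.0  # px; vector-median neighborhood for repair
    repair_threshold: float = 2.0  # normalized-residual cutoff for repair
    ef_step: float = 1.1  # EF multiplier per escalation
    max_ef_escalations: int = 15
    # published stall rule (stop after this many fruitless iterations);
    # the deterministic sweep loop reaches its fixed point after a single
    # empty sweep, which implies any stall limit >= 1
    stall_limit: int = 30

    @property
    def min_half_length(self) -> int:
        return max((self.min_window - 1) // 2, 3)


def seed_points(field: DisplacementField) -> np.ndarray:
    """Indices of the vectors to retrack: failed or filtered-out."""
    return np.nonzero(
        np.isin(field.status, (STATUS_FAILED, STATUS_FILTERED))
    )[0]


class _ConfidentSet:
    """Confident vectors with an incrementally growable KD-tree view."""

    def __init__(self, field: DisplacementField):
        conf = field.confident_mask()
        self.points = field.origins[conf]
        self.vectors = field.vectors[conf]
        self.tree = cKDTree(self.points) if len(self.points) else None
        self._extra_pts: list[np.ndarray] = []
        self._extra_vecs: list[np.ndarray] = []

    def add(self, pt: np.ndarray, vec: np.ndarray) -> None:
        self._extra_pts.append(np.asarray(pt, dtype=float))
        self._extra_vecs.append(np.asarray(vec, dtype=float))

    def query(self, origin: np.ndarray, radius: float) -> np.ndarray:
        """Vectors of all confident neighbors within ``radius``; (k, 2)."""
        hits = []
        if self.tree is not None:
            idx = self.tree.query_ball_point(origin, radius)
            if idx:
                hits.append(self.vectors[idx])
        if self._extra_pts:
            pts = np.asarray(self._extra_pts)
            d = np.hypot(pts[:, 0] - origin[0], pts[:, 1] - origin[1])
            sel = d <= radius
            if sel.any():
                hits.append(np.asarray(self._extra_vecs)[sel])
        if not hits:
            return np.empty((0, 2))
        return np.concatenate(hits, axis=0)

    def count(self, origin: np.ndarray, radius: float) -> int:
        return self.query(origin, radius).shape[0]


def _default_initial_radius(field: DisplacementField) -> float:
    """2 x mean nearest-neighbor spacing of the interrogated bead set."""
    pts = field.origins
    if len(pts) < 2:
        return 10.0
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return 2.0 * float(d[:, 1].mean())


def gather_neighbors(
    confident: "_ConfidentSet | DisplacementField",
    origin: np.ndarray,
    config: RetrackConfig,
    min_neighbors: int | None = None,
    initial_radius: float | None = None,
) -> NeighborStats | None:
    """Grow the search radius until enough confident neighbors are inside.

    Accepts either a :class:`DisplacementField` (its confident vectors
    are used) or the internal incremental confident-set view.  Returns
    None (insufficient) when the maximum radius is reached with fewer
    than ``min_neighbors`` vectors; the seed is then deferred to a later
    iteration when more of its neighborhood has been rescued.
    """
    if isinstance(confident, DisplacementField):
        confident = _ConfidentSet(confident)
    min_nei = config.min_neighbors if min_neighbors is None else min_neighbors
    r0 = initial_radius if initial_radius is not None else 10.0
    r_max = config.max_radius_factor * r0
    r = r0
    while True:
        vecs = confident.query(origin, r)
        if vecs.shape[0] >= min_nei:
            break
        if r >= r_max:
            return None
        r = min(r * config.radius_growth, r_max)
    mags = np.hypot(vecs[:, 0], vecs[:, 1])
    angles = np.arctan2(vecs[:, 1], vecs[:, 0])
    ang_mean, ang_std = _circular_mean_std(angles)
    return NeighborStats(
        n=vecs.shape[0],
        u_nei=np.median(vecs, axis=0),
        mean_vector=vecs.mean(axis=0),
        mag_std=float(mags.std()),
        mag_max=float(mags.max()),
        angle_mean=ang_mean,
        angle_std=ang_std,
        search_radius=float(r),
    )


def masked_score_map(
    smap: ScoreMap,
    stats: NeighborStats,
    ef: float,
    config: RetrackConfig,
) -> ScoreMap:
    """Restrict a score map to shifts compatible with the neighbor model.

    Admissible shifts satisfy  0.5 EF |u_nei| <= |u| <= 3 EF |u_nei|  and
    lie within +/- 2 circular std of the neighbors' mean direction (the
    angular band never collapses below a small floor)."""
    m = stats.model_magnitude
    if m <= 0:
        raise ValueError("masked retracking requires |u_nei| > 0")
    lo = config.mask_mag_range[0] * ef * m
    hi = config.mask_mag_range[1] * ef * m
    band = config.mask_angle_k * max(stats.angle_std, config.angle_std_floor)
    R = smap.u_max
    mag, ang = _polar_grids(R)
    admissible = (mag >= lo) & (mag <= hi)
    admissible &= _ang_diff(ang, stats.angle_mean) <= band
    admissible &= np.isfinite(smap.scores)
    if smap.mask is not None:
        admissible &= smap.mask
    return ScoreMap(scores=smap.scores, u_max=R, mask=admissible)


def select_candidate(
    peaks: list[tuple[float, tuple[int, int]]],
    smap: ScoreMap,
    stats: NeighborStats,
    ef: float,
    config: RetrackConfig,
) -> tuple[float, float, float, str] | None:
    """Pick a displacement from the masked peaks.

    First choice: the masked global maximum, if it passes the peak-ratio
    significance test.  Fallback: the local maximum (not necessarily
    global) closest to the model vector EF * u_nei, accepted only when it
    is close enough in magnitude and direction to the neighborhood.

    Returns (u, v, score, how) with sub-pixel refinement applied, or None.
    """
    ranked = rank_candidates(peaks, smap, stats, ef, config)
    return ranked[0] if ranked else None


def rank_candidates(
    peaks: list[tuple[float, tuple[int, int]]],
    smap: ScoreMap,
    stats: NeighborStats,
    ef: float,
    config: RetrackConfig,
) -> list[tuple[float, float, float, str]]:
    """All acceptable candidates, best first (see :func:`select_candidate`).

    The masked global maximum leads when it passes the significance test;
    the remaining candidates are the closeness-passing local maxima in
    order of distance to the model vector.  Downstream validation
    (reciprocal matching) walks this list and keeps the first survivor.
    """
    if not peaks:
        return []
    out: list[tuple[float, float, float, str]] = []
    seen: set[tuple[int, int]] = set()
    if (
        peaks[0][0] >= config.min_score
        and significance_test(peaks, config.significance, config.significance_mode)
    ):
        score, ipk = peaks[0]
        u, v, _ = subpixel_refine(smap, ipk)
        out.append((u, v, score, "significant"))
        seen.add(ipk)
    model = ef * stats.u_nei
    strong = [p for p in peaks if p[0] >= config.min_score and p[1] not in seen]
    if strong:
        shifts = np.array([p[1] for p in strong], dtype=float)
        scores = np.array([p[0] for p in strong])
        dist = np.hypot(shifts[:, 0] - model[0], shifts[:, 1] - model[1])
        std_eff = max(stats.mag_std, config.mag_std_floor)
        mag_tol = config.mag_accept_k * std_eff
        ang_tol = config.angle_accept_k * max(stats.angle_std, config.angle_std_floor)
        ang = np.arctan2(shifts[:, 1], shifts[:, 0])
        ok = (dist < mag_tol) & (_ang_diff(ang, stats.angle_mean) < ang_tol)
        mags = np.hypot(shifts[:, 0], shifts[:, 1])
        if config.mag_floor_k is not None:
            # a missing vector is expected to be at least as large as its
            # neighbors; reject echo peaks below the neighborhood median
            ok &= mags >= stats.model_magnitude - config.mag_floor_k * std_eff
        if config.mag_cap_k is not None:
            # ... but it should not exceed the largest neighbor by much
            # more than the local spread, whatever the enlargement factor
            ok &= mags <= stats.mag_max + config.mag_cap_k * std_eff
        order = (
            np.lexsort((-scores, dist))
            if config.closest_sort == "distance"
            else np.lexsort((dist, -scores))
        )
        for k in order:
            if not ok[k]:
                continue
            u, v, _ = subpixel_refine(
                smap, (int(shifts[k, 0]), int(shifts[k, 1]))
            )
            out.append((u, v, float(scores[k]), "closest"))
    return out


def retrack_point(
    ref: np.ndarray,
    def_: np.ndarray,
    origin: np.ndarray,
    stats: NeighborStats,
    config: RetrackConfig,
    ef_schedule: tuple[float, ...] = (1.0,),
    base_half_length: int | None = None,
    blacklist: set[tuple[int, int]] | None = None,
    rules: tuple[str, ...] = ("significant", "closest"),
) -> tuple[float, float, float, dict] | None:
    """Attempt to rescue one seed.

    For each enlargement factor of ``ef_schedule`` (in order), the masked
    interrogation is run with a gradually shrinking template window; the
    first candidate that passes selection (and the optional reciprocal
    validation) wins, and is then re-measured at the single-bead window.
    The raw correlation maps are independent of EF, so they are computed
    once per window size at the largest search extent the schedule can
    need and reused across the whole schedule.

    ``blacklist`` holds integer shifts that previous repair rounds
    rejected for this seed; candidates within 1 px of one are skipped.

    Returns (u, v, score, provenance) or None.
    """
    if stats.model_magnitude <= 0:
        return None
    hi_max = config.mask_mag_range[1] * max(ef_schedule) * stats.model_magnitude
    u_eff = int(min(max(config.u_max, math.ceil(hi_max)), config.max_search))
    L0 = config.base_half_length if base_half_length is None else base_half_length
    step = max(config.window_shrink_px // 2, 1)
    sizes = list(range(L0, config.min_half_length - 1, -step))
    maps: dict[int, ScoreMap | None] = {}
    bw_cache: dict[tuple[int, int], tuple[float, float, float]] = {}

    def banned(u, v):
        if not blacklist:
            return False
        return any(
            abs(round(u) - bu) <= 1 and abs(round(v) - bv) <= 1
            for bu, bv in blacklist
        )

    def finalize(u, v, score, how, ef, L):
        if L > config.min_half_length:
            # re-measure at the single-bead window: the large-window score
            # peak is biased by the displacement gradient across the
            # template, the per-bead peak is not
            fine = _refine_at_min_window(ref, def_, origin, (u, v), u_eff, config, maps)
            if fine is not None:
                u, v, score = fine
        prov = {
            "window": 2 * L + 1,
            "ef": ef,
            "n_neighbors": stats.n,
            "search_radius": stats.search_radius,
            "rule": how,
            "u_nei": (float(stats.u_nei[0]), float(stats.u_nei[1])),
            "mag_std": stats.mag_std,
            "angle_std": stats.angle_std,
        }
        return u, v, score, prov

    ranked_cache: dict[tuple[float, int], list] = {}

    def get_ranked(ef, L):
        key = (ef, L)
        if key not in ranked_cache:
            if L not in maps:
                maps[L] = ncc_score_map(
                    ref, def_, TemplateSpec(L, (origin[0], origin[1])), u_eff
                )
            smap = maps[L]
            if smap is None:
                ranked_cache[key] = []
            else:
                masked = masked_score_map(smap, stats, ef, config)
                peaks = find_local_maxima(masked)
                ranked_cache[key] = rank_candidates(peaks, masked, stats, ef, config)
        return ranked_cache[key]

    def search_ef(ef):
        if config.rule_order == "interleaved":
            # per window: dominant masked global first, else closest peak
            for L in sizes:
                for u, v, score, how in get_ranked(ef, L)[: config.max_candidates]:
                    if how not in rules or banned(u, v):
                        continue
                    if (
                        how == "closest"
                        and config.closest_max_half_length is not None
                        and L > config.closest_max_half_length
                    ):
                        continue
                    return (u, v, score, how, ef, L)
            return None
        # significance rule: big-to-small windows (dominance needs texture)
        for L in sizes:
            ranked = get_ranked(ef, L)
            if ranked and ranked[0][3] == "significant" and not banned(
                ranked[0][0], ranked[0][1]
            ):
                u, v, score, how = ranked[0]
                return (u, v, score, how, ef, L)
        # closest-to-model rule, window order per config
        order = sizes if config.closest_window_order == "big" else sizes[::-1]
        for L in order:
            for u, v, score, how in get_ranked(ef, L)[: config.max_candidates]:
                if how != "closest" or banned(u, v):
                    continue
                return (u, v, score, how, ef, L)
        return None

    # one candidate per EF level, first acceptable in rule order
    collected: list[tuple[float, float, float, str, float, int]] = []
    seen_shifts: set[tuple[int, int]] = set()
    for ef in ef_schedule:
        found = search_ef(ef)
        if found is None:
            continue
        u, v, score, how, ef_, L = found
        if how == "significant" and ef_ == ef_schedule[0]:
            # a dominant masked global at the un-enlarged model needs no
            # arbitration — this is the trustworthy, common case
            return finalize(u, v, score, how, ef_, L)
        key = (int(round(u)), int(round(v)))
        if key not in seen_shifts:
            seen_shifts.add(key)
            collected.append(found)
    if not collected:
        return None
    if len(collected) == 1 or not config.backward_check:
        return finalize(*collected[0])
    # distinct EF levels point at different peaks: arbitrate with the
    # reciprocal-match evidence (the true correspondence scores high when
    # its deformed-image patch is correlated back to the seed origin)
    best = None
    for cand in collected:
        u, v = cand[0], cand[1]
        key = (int(round(u)), int(round(v)))
        if key not in bw_cache:
            bw_cache[key] = backward_match(ref, def_, origin, (u, v), config)
        g_off, b2, _ = bw_cache[key]
        if np.isnan(g_off):
            return finalize(*collected[0])  # border: keep schedule order
        if best is None or b2 > best[0]:
            best = (b2, cand)
    return finalize(*best[1])


def backward_match(
    ref: np.ndarray,
    def_: np.ndarray,
    origin: np.ndarray,
    uv: tuple[float, float],
    config: RetrackConfig,
) -> tuple[float, float, float]:
    """Reciprocal-match evidence for a candidate displacement.

    A genuine correspondence is symmetric: the single-bead template taken
    from the *deformed* image at the matched position must correlate back
    to the seed origin in the reference image.  An accidental texture
    match ("echo" peak produced by a different bead) correlates back to
    that other bead's reference position instead.

    Returns ``(g_off, b2, g)``: the offset of the backward global maximum
    from the seed origin, the best backward score within
    ``backward_tol`` px of the origin, and the backward global score.
    Indeterminate geometry (borders) yields ``(nan, nan, nan)``.
    """
    nan3 = (float("nan"),) * 3
    L = config.min_half_length
    W = config.backward_search
    h, w = ref.shape
    cx = int(round(origin[0]))
    cy = int(round(origin[1]))
    mx = int(round(origin[0] + uv[0]))
    my = int(round(origin[1] + uv[1]))
    # sub-pixel residue of the accepted shift relative to integer centers
    rx = (origin[0] + uv[0]) - mx - (origin[0] - cx)
    ry = (origin[1] + uv[1]) - my - (origin[1] - cy)
    if not (L <= mx < w - L and L <= my < h - L):
        return nan3  # matched patch outside the deformed image
    tpl = def_[my - L : my + L + 1, mx - L : mx + L + 1]
    if np.ptp(tpl) == 0:
        return (float("inf"), -1.0, 1.0)  # flat patch: no evidence, fail
    # backward search region around the seed origin, clipped at borders
    y0, y1 = max(cy - L - W, 0), min(cy + L + W + 1, h)
    x0, x1 = max(cx - L - W, 0), min(cx + L + W + 1, w)
    if (y1 - y0) < 2 * L + 1 or (x1 - x0) < 2 * L + 1:
        return nan3  # no usable search window at the border
    from skimage.feature import match_template

    res = match_template(ref[y0:y1, x0:x1], tpl, pad_input=False)
    # response index (i, j) -> ref window center (x0+j+L, y0+i+L);
    # backward disagreement is its offset from the seed origin
    yy, xx = np.mgrid[0 : res.shape[0], 0 : res.shape[1]]
    bdist = np.hypot(xx + x0 + L - cx + rx, yy + y0 + L - cy + ry)
    near = bdist <= config.backward_tol
    if not near.any():
        return nan3  # origin outside the visible backward search
    iy, ix = np.unravel_index(np.argmax(res), res.shape)
    return float(bdist[iy, ix]), float(res[near].max()), float(res.max())


def backward_consistent(
    ref: np.ndarray,
    def_: np.ndarray,
    origin: np.ndarray,
    uv: tuple[float, float],
    config: RetrackConfig,
) -> bool:
    """Strict reciprocal validation: the backward global maximum must land
    on the seed origin (indeterminate geometry passes)."""
    g_off, _, _ = backward_match(ref, def_, origin, uv, config)
    return bool(np.isnan(g_off) or g_off <= config.backward_tol)


def _refine_at_min_window(
    ref: np.ndarray,
    def_: np.ndarray,
    origin: np.ndarray,
    accepted: tuple[float, float],
    u_eff: int,
    config: RetrackConfig,
    maps: dict | None = None,
) -> tuple[float, float, float] | None:
    """Snap an accepted shift to the nearest single-bead-window peak.

    Returns the refined (u, v, score) when a sufficiently strong local
    maximum exists within ``refine_snap`` px of the accepted shift on the
    minimum-window score map; otherwise None (keep the original)."""
    Lm = config.min_half_length
    if maps is not None and Lm in maps:
        smap = maps[Lm]
    else:
        smap = ncc_score_map(
            ref, def_, TemplateSpec(Lm, (origin[0], origin[1])), u_eff
        )
        if maps is not None:
            maps[Lm] = smap
    if smap is None:
        return None
    peaks = find_local_maxima(smap)
    if not peaks:
        return None
    shifts = np.array([p[1] for p in peaks], dtype=float)
    scores = np.array([p[0] for p in peaks])
    d = np.hypot(shifts[:, 0] - accepted[0], shifts[:, 1] - accepted[1])
    ok = (d <= config.refine_snap) & (scores >= config.min_score)
    if not ok.any():
        return None
    k = int(np.nonzero(ok)[0][np.argmin(d[ok])])
    u, v, _ = subpixel_refine(smap, (int(shifts[k, 0]), int(shifts[k, 1])))
    return u, v, float(scores[k])


def _ef_schedule(config: RetrackConfig) -> tuple[float, ...]:
    """EF ladder 1.0, 1.1, 1.21, ... (10% per escalation)."""
    return tuple(
        config.ef_step**k for k in range(config.max_ef_escalations + 1)
    )


def _cascade(
    ref: np.ndarray,
    def_: np.ndarray,
    field: DisplacementField,
    cfg: RetrackConfig,
    ef_schedule: tuple[float, ...],
    min_neighbors: int | None,
    base_half_length: int | None,
    log: list | None,
    _state: dict,
    rules: tuple[str, ...] = ("significant", "closest"),
) -> DisplacementField:
    """One retracking cascade to its fixed point (internal).

    Seeds are visited best-constrained first (most confident neighbors),
    and every success immediately joins the confident set, so missing
    regions fill inward from their rim.  The loop is deterministic: a
    full sweep that rescues nothing is a fixed point and terminates it
    (a stall counter could never recover once a sweep is empty), and
    failed attempts are not repeated until the seed's confident
    neighborhood has changed.
    """
    out = field.copy()
    r0 = (
        cfg.initial_radius
        if cfg.initial_radius is not None
        else _default_initial_radius(out)
    )
    seeds = list(seed_points(out))
    confident = _ConfidentSet(out)
    attempted: dict[int, tuple] = _state.setdefault("attempted", {})
    blacklists: dict[int, set] = _state.setdefault("blacklists", {})
    sweep = _state.get("sweep", 0)
    sched_key = (len(ef_schedule), rules)
    while seeds:
        sweep += 1
        # rim-first visitation: most confident neighbors first
        counts = [confident.count(out.origins[i], 2.0 * r0) for i in seeds]
        order = np.argsort(-np.asarray(counts), kind="stable")
        rescued = False
        for oi in order:
            i = seeds[oi]
            origin = out.origins[i]
            n_near = confident.count(origin, cfg.max_radius_factor * r0)
            sig = (sched_key, base_half_length, min_neighbors, n_near)
            if attempted.get(i) == sig:
                continue  # nothing changed since the last failed attempt
            stats = gather_neighbors(
                confident, origin, cfg, min_neighbors, initial_radius=r0
            )
            if stats is None or stats.model_magnitude <= 0:
                attempted[i] = sig
                continue
            res = retrack_point(
                ref,
                def_,
                origin,
                stats,
                cfg,
                ef_schedule,
                base_half_length,
                blacklist=blacklists.get(i),
                rules=rules,
            )
            if res is None:
                attempted[i] = sig
                continue
            u, v, score, prov = res
            out.u[i], out.v[i], out.score[i] = u, v, score
            out.status[i] = STATUS_RETRACKED
            confident.add(origin, np.array([u, v]))
            rescued = True
            if log is not None:
                log.append({"seed": int(i), "sweep": sweep, **prov})
        if not rescued:
            break
        seeds = [i for i in seeds if out.status[i] in (STATUS_FAILED, STATUS_FILTERED)]
    _state["sweep"] = sweep
    out.provenance.setdefault("retrack", {})
    out.provenance["retrack"].update(
        {
            "max_ef": max(ef_schedule),
            "sweeps": sweep,
            "seeds_left": len(seeds),
        }
    )
    return out


def _flag_inconsistent_retracked(
    field: DisplacementField,
    cfg: RetrackConfig,
    material=None,
    fov: tuple[int, int] | None = None,
) -> np.ndarray:
    """Indices of retracked vectors that disagree with their neighborhood.

    ``repair_mode='elastic'`` exploits the physics of the substrate: the
    confident field is gridded, inverted to a lightly regularized
    traction field and pushed back through the Boussinesq operator,
    which acts as a smoother that *can* represent the steep 1/r response
    around a concentrated force (a local polynomial fit cannot).
    Retracked vectors deviating more than ``repair_abs_tol`` px from the
    elastic prediction are flagged.  Falls back to the normalized
    vector-median test (``'median'``) when no material is given;
    ``'affine'`` flags against a robust local first-order fit.
    """
    if cfg.repair_mode in ("median", "elastic"):
        from .tracking import vector_median_filter

        checked = vector_median_filter(
            field, cfg.repair_radius, cfg.repair_threshold
        )
        return np.nonzero(
            (checked.status == STATUS_FILTERED)
            & (field.status == STATUS_RETRACKED)
        )[0]
    conf = field.confident_mask()
    cidx = np.nonzero(conf)[0]
    pts = field.origins[cidx]
    vecs = field.vectors[cidx]
    tree = cKDTree(pts)
    flagged = []
    for i in np.nonzero(field.status == STATUS_RETRACKED)[0]:
        origin = field.origins[i]
        nb = [j for j in tree.query_ball_point(origin, cfg.repair_radius)
              if cidx[j] != i]
        if len(nb) < 6:
            continue
        X = np.column_stack([np.ones(len(nb)), pts[nb] - origin])
        Y = vecs[nb]
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = np.hypot(*(Y - X @ coef).T)
        mad = np.median(resid) + 1e-9
        keep = resid <= 3.0 * mad
        if keep.sum() >= 6:
            coef, *_ = np.linalg.lstsq(X[keep], Y[keep], rcond=None)
        pred = coef[0]  # affine prediction at the origin
        if np.hypot(*(field.vectors[i] - pred)) > cfg.repair_abs_tol:
            flagged.append(i)
    return np.asarray(flagged, dtype=int)


def _elastic_prediction(
    field: DisplacementField,
    cfg: RetrackConfig,
    material,
    fov: tuple[int, int],
    points: np.ndarray,
) -> np.ndarray | None:
    """Elastic smoother of the confident field, evaluated at ``points``.

    The field is gridded, inverted to a lightly regularized traction and
    pushed back through the Boussinesq operator — a smoother that *can*
    represent the steep 1/r response around a concentrated force (a
    local polynomial fit cannot).  The k = 0 mode carries no traction
    information, so the mean displacement is restored explicitly.
    """
    from scipy.interpolate import RegularGridInterpolator

    from .inversion import _solve_fourier, fourier_kernel, interpolate_to_grid

    g = cfg.repair_grid
    try:
        ug, vg, spacing = interpolate_to_grid(field, (g, g), fov)
    except ValueError:
        return None
    tx, ty, _, _ = _solve_fourier(ug, vg, spacing, material, cfg.repair_lambda)
    gxx, gyy, gxy = fourier_kernel((g, g), spacing, material)
    ftx, fty = np.fft.fft2(tx), np.fft.fft2(ty)
    ue = np.real(np.fft.ifft2(gxx * ftx + gxy * fty)) + ug.mean()
    ve = np.real(np.fft.ifft2(gxy * ftx + gyy * fty)) + vg.mean()
    gx = (np.arange(g) + 0.5) * spacing - 0.5
    gy = (np.arange(g) + 0.5) * (fov[0] / g) - 0.5
    itpu = RegularGridInterpolator((gy, gx), ue, bounds_error=False, fill_value=None)
    itpv = RegularGridInterpolator((gy, gx), ve, bounds_error=False, fill_value=None)
    pts = np.array(points[:, ::-1], dtype=float)  # (y, x)
    pts[:, 0] = np.clip(pts[:, 0], gy[0], gy[-1])
    pts[:, 1] = np.clip(pts[:, 1], gx[0], gx[-1])
    return np.column_stack([itpu(pts), itpv(pts)])


def _flag_elastic(
    field: DisplacementField,
    cfg: RetrackConfig,
    material,
    fov: tuple[int, int],
) -> np.ndarray:
    """Retracked vectors deviating from the elastic smoother; see
    :func:`_flag_inconsistent_retracked`."""
    ret = np.nonzero(field.status == STATUS_RETRACKED)[0]
    if ret.size == 0:
        return ret
    pred = _elastic_prediction(field, cfg, material, fov, field.origins[ret])
    if pred is None:
        return np.empty(0, dtype=int)
    resid = np.hypot(field.u[ret] - pred[:, 0], field.v[ret] - pred[:, 1])
    return ret[resid > cfg.repair_abs_tol]


def _match_near_prediction(
    ref: np.ndarray,
    def_: np.ndarray,
    origin: np.ndarray,
    pred: np.ndarray,
    cfg: RetrackConfig,
) -> tuple[float, float, float] | None:
    """Single-bead-window peak nearest an elastic prediction (<= snap px)."""
    u_eff = int(min(max(cfg.u_max, math.ceil(np.hypot(*pred)) + 6), cfg.max_search))
    smap = ncc_score_map(
        ref, def_, TemplateSpec(cfg.min_half_length, (origin[0], origin[1])), u_eff
    )
    if smap is None:
        return None
    peaks = find_local_maxima(smap)
    if not peaks:
        return None
    shifts = np.array([p[1] for p in peaks], dtype=float)
    scores = np.array([p[0] for p in peaks])
    d = np.hypot(shifts[:, 0] - pred[0], shifts[:, 1] - pred[1])
    ok = (d <= cfg.refine_snap) & (scores >= cfg.min_score)
    if not ok.any():
        return None
    k = int(np.nonzero(ok)[0][np.argmin(d[ok])])
    u, v, _ = subpixel_refine(smap, (int(shifts[k, 0]), int(shifts[k, 1])))
    return u, v, float(scores[k])


def _elastic_repair(
    ref: np.ndarray,
    def_: np.ndarray,
    field: DisplacementField,
    cfg: RetrackConfig,
    material,
    log: list | None,
) -> DisplacementField:
    """Final consistency pass against the substrate's elasticity.

    Retracked vectors that disagree with the elastic smoother of the
    completed field are re-matched to the correlation peak nearest the
    smoother's prediction; vectors with no such peak are revoked.  The
    smoother is rebuilt between rounds as the field improves.  Applied
    only to a converged field — on a field with unresolved holes the
    smoother underestimates and would revoke genuine vectors.
    """
    out = field.copy()
    # a single pass: the smoother is only trustworthy on the completed
    # field, and revocations would degrade it for any further round
    flagged = _flag_elastic(out, cfg, material, ref.shape)
    if flagged.size == 0:
        return out
    preds = _elastic_prediction(out, cfg, material, ref.shape, out.origins[flagged])
    if preds is None:
        return out
    n_rematched = n_revoked = 0
    for i, pred in zip(flagged, preds):
        res = _match_near_prediction(ref, def_, out.origins[i], pred, cfg)
        if res is None:
            out.u[i] = np.nan
            out.v[i] = np.nan
            out.score[i] = np.nan
            out.status[i] = STATUS_FAILED
            n_revoked += 1
        else:
            out.u[i], out.v[i], out.score[i] = res
            n_rematched += 1
    if log is not None:
        log.append(
            {
                "event": "elastic_repair",
                "flagged": int(flagged.size),
                "rematched": n_rematched,
                "revoked": n_revoked,
            }
        )
    return out


def _repair(
    ref: np.ndarray,
    def_: np.ndarray,
    out: DisplacementField,
    cfg: RetrackConfig,
    rerun,
    state: dict,
    log: list | None,
) -> DisplacementField:
    """Iteratively re-examine the retracked vectors.

    A rescued vector that disagrees with its (now much more complete)
    neighborhood by the vector-median criterion was most likely an
    accidental texture match accepted while the neighborhood model still
    lagged.  Such vectors are revoked, their shifts blacklisted for
    their seeds, and the cascade reruns so the matured neighborhood can
    guide them to a different peak.  Bounded by ``repair_rounds``.
    """
    for rnd in range(cfg.repair_rounds):
        bad = _flag_inconsistent_retracked(out, cfg)
        if bad.size == 0:
            break
        blacklists = state.setdefault("blacklists", {})
        for i in bad:
            blacklists.setdefault(int(i), set()).add(
                (int(round(out.u[i])), int(round(out.v[i])))
            )
            out.u[i] = np.nan
            out.v[i] = np.nan
            out.score[i] = np.nan
            out.status[i] = STATUS_FILTERED
            state.get("attempted", {}).pop(int(i), None)
        if log is not None:
            log.append({"event": "repair", "round": rnd, "revoked": int(bad.size)})
        out = rerun(out)
    return out


def retrack_field(
    ref: np.ndarray,
    def_: np.ndarray,
    field: DisplacementField,
    config: RetrackConfig | None = None,
    ef_schedule: tuple[float, ...] = (1.0,),
    min_neighbors: int | None = None,
    base_half_length: int | None = None,
    log: list | None = None,
    material=None,
    _state: dict | None = None,
) -> DisplacementField:
    """Neighbor-guided retracking of every seed point (median model).

    Runs the rim-inward cascade to its fixed point, then revokes and
    re-queues retracked vectors that the vector-median consistency test
    rejects (see :func:`_repair`).  With the default single-entry
    ``ef_schedule`` the model vector is the plain neighborhood median —
    the cPTVR-median variant.
    """
    cfg = config if config is not None else RetrackConfig()
    state = _state if _state is not None else {"attempted": {}, "sweep": 0}
    # phase 1: exhaust the trustworthy significance-rule rescues so the
    # confident set is as dense as possible before any closest-to-model
    # acceptance has to gamble on a non-dominant peak
    out = _cascade(
        ref, def_, field, cfg, ef_schedule, min_neighbors, base_half_length,
        log, state, rules=("significant",),
    )
    out = _cascade(
        ref, def_, out, cfg, ef_schedule, min_neighbors, base_half_length, log, state
    )
    if _state is None:  # standalone call: repair here
        out = _repair(
            ref,
            def_,
            out,
            cfg,
            lambda f: _cascade(
                ref, def_, f, cfg, ef_schedule, min_neighbors,
                base_half_length, log, state,
            ),
            state,
            log,
        )
    return out


def retrack_with_enlargement(
    ref: np.ndarray,
    def_: np.ndarray,
    field: DisplacementField,
    config: RetrackConfig | None = None,
    log: list | None = None,
    material=None,
    start_field_is_median_result: bool = False,
) -> DisplacementField:
    """Adaptive retracking with the enlargement factor.

    Runs the plain median-model retracking to its fixed point first, then
    escalates per remaining seed: the enlargement factor climbs 1.0 ->
    1.1 -> 1.21 -> ... (10% per step, ``max_ef_escalations`` steps) with
    the shrinking-window ladder tried at every EF level, accepting the
    first validated candidate.  When a whole escalated pass rescues
    nothing, the minimum neighbor count for the search-radius
    determination is raised (3 -> 5 -> 8) to firm up the neighborhood
    statistics, and the pass repeats.  Every rescue re-enables its
    still-missing neighbors (their statistics changed), so passes repeat
    until a full ladder of passes is fruitless or no seed remains.
    Termination is guaranteed: seeds are finite, every pass either
    rescues one or advances the finite ladder.

    ``start_field_is_median_result`` skips the initial median phase when
    ``field`` is already the fixed point of :func:`retrack_field`.
    """
    cfg = config if config is not None else RetrackConfig()
    out = field.copy()
    state: dict = {"attempted": {}, "sweep": 0}
    ladder = list(cfg.min_neighbors_ladder)
    schedule = _ef_schedule(cfg)
    events: list[dict] = []

    def escalate(f: DisplacementField) -> DisplacementField:
        while len(seed_points(f)) > 0:
            progressed = False
            for min_nei in ladder:
                before = len(seed_points(f))
                if before == 0:
                    break
                f = _cascade(
                    ref, def_, f, cfg, schedule, min_nei, None, log, state,
                    rules=("significant",),
                )
                f = _cascade(
                    ref, def_, f, cfg, schedule, min_nei, None, log, state
                )
                after = len(seed_points(f))
                events.append(
                    {
                        "event": "ef_pass",
                        "min_neighbors": min_nei,
                        "rescued": before - after,
                    }
                )
                if after < before:
                    progressed = True
                    break  # fresh vectors: restart from the smallest ladder step
            if not progressed:
                break
        return f

    if not start_field_is_median_result:
        out = _cascade(
            ref, def_, out, cfg, (1.0,), ladder[0], None, log, state,
            rules=("significant",),
        )
        out = _cascade(ref, def_, out, cfg, (1.0,), ladder[0], None, log, state)
    out = escalate(out)
    out = _repair(ref, def_, out, cfg, escalate, state, log)
    out.provenance["enlargement"] = {
        "max_ef": max(schedule),
        "ef_escalations": cfg.max_ef_escalations,
        "events": events,
    }
    return out
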