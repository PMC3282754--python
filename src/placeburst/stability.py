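"""Cross-session place-field similarity, rotation search, cue classification.

Similarity is the pixel-by-pixel Pearson correlation between two rate maps
over jointly valid pixels, Fisher-Z transformed for parametric comparisons.
The rotation search rotates the first map about the arena center in 1-degree
steps (nearest-neighbor resampling) and reports the angle that maximizes the
correlation with the second map; the reported ``best_angle`` is therefore the
angular displacement of the field from the first session to the second, which
is the quantity the cue-following classification compares with the cue-card
rotation.  Resampling is nearest-neighbor rather than bilinear so the search
does not manufacture smoothness that inflates the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .exceptions import DegenerateOverlapError, GeometryMismatchError
from .maps import RateMap, domain_mask
from .spatial_metrics import fisher_z

MIN_JOINT_PIXELS = 10


class CueClass(str, Enum):
    DISTAL = "DistalCue"
    LOCAL = "LocalCue"
    REMAP = "Remap"


@dataclass
class SimilarityResult:
    r: float
    z: float
    n_pixels: int


@dataclass
class RotationResult:
    best_angle: float  # degrees in [0, 360), CCW displacement of the field
    max_r: float
    max_z: float
    abs_rotation: float  # degrees in [0, 180], direction-folded

    @staticmethod
    def fold(angle: float) -> float:
        """Fold an angle to absolute rotation in [0, 180]."""
        a = angle % 360.0
        return min(a, 360.0 - a)


def _joint_values(a: RateMap, b: RateMap) -> tuple[np.ndarray, np.ndarray]:
    if not a.same_geometry(b):
        raise GeometryMismatchError("rate maps have different grid geometry")
    joint = a.valid & b.valid
    return a.rate[joint], b.rate[joint]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < MIN_JOINT_PIXELS:
        raise DegenerateOverlapError(f"only {len(x)} jointly valid pixels (< {MIN_JOINT_PIXELS})")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateOverlapError("zero variance over jointly valid pixels")
    return float(stats.pearsonr(x, y).statistic)


def map_similarity(a: RateMap, b: RateMap) -> SimilarityResult:
    """Pearson r (and Fisher Z) over pixels valid in both maps."""
    x, y = _joint_values(a, b)
    r = _pearson(x, y)
    return SimilarityResult(r=r, z=fisher_z(r), n_pixels=len(x))


# ---------------------------------------------------------------------------
# Rotation search.  For each angle we need, per target pixel, the source pixel
# whose center maps onto it under the inverse rotation; these index maps depend
# only on grid geometry and are cached across calls.
# ---------------------------------------------------------------------------

_rotation_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _rotation_tables(n: int, pixel_size: float, arena_radius: float, step: float):
    """(flat source index, in-domain mask) per angle, shape (n_angles, n*n)."""
    key = (n, pixel_size, arena_radius, step)
    if key in _rotation_cache:
        return _rotation_cache[key]
    x0 = -n * pixel_size / 2.0
    c = x0 + (np.arange(n) + 0.5) * pixel_size
    cx = np.repeat(c, n)  # row-major [i, j]: x varies with i
    cy = np.tile(c, n)
    angles = np.arange(0.0, 360.0, step)
    th = np.radians(angles)
    cos_t, sin_t = np.cos(th), np.sin(th)
    # rotating the map by +theta CCW: value at target p comes from R(-theta) p
    sx = cos_t[:, None] * cx[None, :] + sin_t[:, None] * cy[None, :]
    sy = -sin_t[:, None] * cx[None, :] + cos_t[:, None] * cy[None, :]
    si = np.floor((sx - x0) / pixel_size).astype(np.int32)
    sj = np.floor((sy - x0) / pixel_size).astype(np.int32)
    inside = (si >= 0) & (si < n) & (sj >= 0) & (sj < n)
    si = np.clip(si, 0, n - 1)
    sj = np.clip(sj, 0, n - 1)
    flat = si * n + sj
    dom = domain_mask(arena_radius, pixel_size).ravel()
    ok = inside & dom[flat] & dom[None, :]
    _rotation_cache[key] = (flat, ok)
    return flat, ok


def rotate_map(ratemap: RateMap, angle_deg: float) -> RateMap:
    """Rotate a map CCW about the arena center, nearest-neighbor resampled.

    Target pixels whose source falls outside the grid or the circular domain
    are invalid.
    """
    n = ratemap.n
    step = 1.0
    # build tables for arbitrary angle directly (no cache) if not a whole step
    if angle_deg % step == 0.0:
        flat, ok = _rotation_tables(n, ratemap.pixel_size, ratemap.arena_radius, step)
        k = int((angle_deg % 360.0) / step)
        src, valid_src = flat[k], ok[k]
    else:
        x0 = ratemap.x0
        c = x0 + (np.arange(n) + 0.5) * ratemap.pixel_size
        cx = np.repeat(c, n)
        cy = np.tile(c, n)
        t = np.radians(angle_deg)
        sx = np.cos(t) * cx + np.sin(t) * cy
        sy = -np.sin(t) * cx + np.cos(t) * cy
        si = np.floor((sx - x0) / ratemap.pixel_size).astype(int)
        sj = np.floor((sy - x0) / ratemap.pixel_size).astype(int)
        inside = (si >= 0) & (si < n) & (sj >= 0) & (sj < n)
        si, sj = np.clip(si, 0, n - 1), np.clip(sj, 0, n - 1)
        src = si * n + sj
        dom = domain_mask(ratemap.arena_radius, ratemap.pixel_size).ravel()
        valid_src = inside & dom[src] & dom
    rate = ratemap.rate.ravel()[src].reshape(n, n)
    occ = ratemap.occupancy.ravel()[src].reshape(n, n)
    valid = (ratemap.valid.ravel()[src] & valid_src).reshape(n, n)
    return RateMap(
        rate=np.where(valid, rate, 0.0),
        occupancy=np.where(valid, occ, 0.0),
        valid=valid,
        pixel_size=ratemap.pixel_size,
        arena_radius=ratemap.arena_radius,
    )


def best_rotation(a: RateMap, b: RateMap, step: float = 1.0) -> RotationResult:
    """Angle (CCW, degrees) by which map ``a`` must be rotated to best match ``b``.

    Scans {0, step, ..., 360-step} degrees; Pearson r on jointly valid pixels
    per angle; ties broken toward the smallest angle.  Angles with a
    degenerate overlap (too few pixels, zero variance) are skipped.
    """
    if not a.same_geometry(b):
        raise GeometryMismatchError("rate maps have different grid geometry")
    n = a.n
    flat, ok = _rotation_tables(n, a.pixel_size, a.arena_radius, step)
    a_rate = a.rate.ravel()
    a_valid = a.valid.ravel()
    b_rate = b.rate.ravel()
    b_valid = b.valid.ravel()
    angles = np.arange(0.0, 360.0, step)
    best_r = -np.inf
    best_angle = None
    any_valid = False
    for k in range(len(angles)):
        src = flat[k]
        joint = ok[k] & a_valid[src] & b_valid
        m = int(joint.sum())
        if m < MIN_JOINT_PIXELS:
            continue
        x = a_rate[src[joint]]
        y = b_rate[joint]
        sx = x.std()
        sy = y.std()
        if sx == 0.0 or sy == 0.0:
            continue
        any_valid = True
        r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
        if r > best_r:
            best_r = r
            best_angle = float(angles[k])
    if not any_valid:
        raise DegenerateOverlapError("no rotation angle yields a well-defined correlation")
    return RotationResult(
        best_angle=best_angle,
        max_r=best_r,
        max_z=fisher_z(best_r),
        abs_rotation=RotationResult.fold(best_angle),
    )


def classify_cue_following(rotation: RotationResult, card_rotation: float) -> CueClass:
    """Classify a session pair by what the field followed.

    ``card_rotation`` is the cue-card rotation between the two sessions,
    degrees CCW in (-180, 180].  A field whose displacement stays within a
    90-degree-wide arc (+/- 45 degrees) of 0 follows the distal cue; within
    the same arc of the card rotation it follows the local cue; otherwise it
    remapped.  The exact 45-degree boundary falls to Remap (half-open window).
    """
    d0 = RotationResult.fold(rotation.best_angle)
    dc = RotationResult.fold(rotation.best_angle - card_rotation)
    if d0 < 45.0:
        return CueClass.DISTAL
    if dc < 45.0:
        return CueClass.LOCAL
    return CueClass.REMAP


def random_pair_baseline(maps: list[RateMap], n_pairs: int, seed: int) -> np.ndarray:
    """Fisher-Z similarities of randomly picked distinct-cell map pairs.

    Pairs are sampled without replacement when enough distinct pairs exist;
    degenerate pairs (no joint overlap) are skipped.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps for a random-pair baseline")
    rng = np.random.default_rng(seed)
    all_pairs = [(i, j) for i in range(len(maps)) for j in range(i + 1, len(maps))]
    if n_pairs >= len(all_pairs):
        chosen = all_pairs
    else:
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        chosen = [all_pairs[i] for i in idx]
    zs = []
    for i, j in chosen:
        try:
            zs.append(map_similarity(maps[i], maps[j]).z)
        except DegenerateOverlapError:
            continue
    return np.asarray(zs)
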