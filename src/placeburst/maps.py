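"""Occupancy-normalized rate maps on a 1x1 cm grid, and place-field definitions.

The grid is axis-aligned and arena-centered: pixel (i, j) covers the half-open
square [x0 + i*s, x0 + (i+1)*s) x [y0 + j*s, y0 + (j+1)*s) cm with
x0 = y0 = -n*s/2 and s the pixel size.  Pixels wholly outside the circular
arena are permanently invalid; for a 30-cm arena at 1-cm pixels this leaves
roughly 700 in-domain pixels.  Visited-but-silent pixels carry rate 0; pixels
with occupancy below ``min_occupancy`` are invalid and excluded from every
downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import EmptyFieldError
from .io import PositionTrack, SpikeTrain

DEFAULT_MIN_OCCUPANCY = 0.1  # s; suppresses single-sample rate spikes


def grid_size(arena_radius: float, pixel_size: float = 1.0) -> int:
    """Number of pixels per side for a grid covering the arena."""
    return int(np.ceil(2.0 * arena_radius / pixel_size))


def domain_mask(arena_radius: float, pixel_size: float = 1.0) -> np.ndarray:
    """Boolean (n, n) mask of pixels that intersect the circular arena.

    A pixel is in-domain unless it lies wholly outside the circle, i.e. the
    closest point of its square to the arena center is farther than the radius.
    """
    n = grid_size(arena_radius, pixel_size)
    x0 = -n * pixel_size / 2.0
    lo = x0 + np.arange(n) * pixel_size
    hi = lo + pixel_size
    # distance from origin to nearest point of interval [lo, hi] per axis
    dx = np.maximum(np.maximum(lo, -hi), 0.0)
    d2 = dx[:, None] ** 2 + dx[None, :] ** 2
    return d2 <= arena_radius**2


@dataclass
class RateMap:
    """Firing rate (Hz), occupancy (s), and validity on a square-pixel grid.

    Arrays are indexed ``[i, j]`` with i the x-pixel and j the y-pixel.
    """

    rate: np.ndarray
    occupancy: np.ndarray
    valid: np.ndarray
    pixel_size: float
    arena_radius: float

    @property
    def n(self) -> int:
        return self.rate.shape[0]

    @property
    def x0(self) -> float:
        return -self.n * self.pixel_size / 2.0

    def same_geometry(self, other: "RateMap") -> bool:
        return (
            self.rate.shape == other.rate.shape
            and self.pixel_size == other.pixel_size
            and self.arena_radius == other.arena_radius
        )

    def pixel_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) pixel indices of points (x, y) cm, clipped to the grid."""
        i = np.floor((np.asarray(x) - self.x0) / self.pixel_size).astype(int)
        j = np.floor((np.asarray(y) - self.x0) / self.pixel_size).astype(int)
        return np.clip(i, 0, self.n - 1), np.clip(j, 0, self.n - 1)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(n, n) arrays of pixel-center x and y coordinates in cm."""
        c = self.x0 + (np.arange(self.n) + 0.5) * self.pixel_size
        return np.broadcast_to(c[:, None], (self.n, self.n)).copy(), np.broadcast_to(
            c[None, :], (self.n, self.n)
        ).copy()

    def mean_rate(self) -> float:
        """Mean firing rate over valid pixels (unweighted pixel mean)."""
        if not self.valid.any():
            raise EmptyFieldError("rate map has no valid pixels")
        return float(self.rate[self.valid].mean())

    def to_dense(self) -> np.ndarray:
        """Dense (n, n) rate matrix with NaN marking invalid pixels."""
        out = np.where(self.valid, self.rate, np.nan)
        return out

    def export(self, path) -> None:
        """Write the dense rate matrix (rows = x-pixels) as CSV, NaN = invalid."""
        np.savetxt(path, self.to_dense(), delimiter=",", fmt="%.6g")


@dataclass
class PlaceField:
    """Set of pixels forming the firing field, with the defining rule."""

    member: np.ndarray  # boolean (n, n)
    definition_mode: str  # "above_mean" | "top_quartile"
    size: int = field(init=False)

    def __post_init__(self) -> None:
        self.size = int(self.member.sum())

    def contains(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        return self.member[i, j]


def compute_rate_map(
    spikes: SpikeTrain,
    track: PositionTrack,
    arena_radius: float,
    pixel_size: float = 1.0,
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
) -> RateMap:
    """Occupancy-normalized firing-rate map.

    Each spike is assigned to the pixel of the temporally nearest track
    sample; each track sample contributes one sample interval of dwell time
    to its pixel.  Per pixel, rate = spike count / dwell time.
    """
    if len(track) == 0:
        raise EmptyFieldError("empty position track")
    n = grid_size(arena_radius, pixel_size)
    dom = domain_mask(arena_radius, pixel_size)
    rm = RateMap(
        rate=np.zeros((n, n)),
        occupancy=np.zeros((n, n)),
        valid=dom.copy(),
        pixel_size=pixel_size,
        arena_radius=arena_radius,
    )
    dt = track.sample_interval
    ti, tj = rm.pixel_index(track.x, track.y)
    np.add.at(rm.occupancy, (ti, tj), dt)
    counts = np.zeros((n, n))
    if len(spikes) > 0:
        sx, sy = track.position_at(spikes.times)
        si, sj = rm.pixel_index(sx, sy)
        np.add.at(counts, (si, sj), 1.0)
    rm.valid &= rm.occupancy >= min_occupancy
    with np.errstate(divide="ignore", invalid="ignore"):
        rm.rate = np.where(rm.valid, counts / np.where(rm.occupancy > 0, rm.occupancy, np.inf), 0.0)
    return rm


def define_place_field(ratemap: RateMap, mode: str = "above_mean") -> PlaceField:
    """Place field of a rate map.

    ``above_mean``: valid pixels whose rate strictly exceeds the mean rate
    over valid pixels (the field-size definition used for place-field area).
    ``top_quartile``: the 25% of valid pixels with the highest rate, ties
    broken by flat pixel index order (row-major, lower index first).
    """
    if not ratemap.valid.any():
        raise EmptyFieldError("rate map has no valid pixels")
    member = np.zeros_like(ratemap.valid)
    if mode == "above_mean":
        member = ratemap.valid & (ratemap.rate > ratemap.mean_rate())
    elif mode == "top_quartile":
        flat_idx = np.flatnonzero(ratemap.valid.ravel())
        rates = ratemap.rate.ravel()[flat_idx]
        k = int(round(0.25 * len(flat_idx)))
        k = max(k, 1)
        # stable sort: descending rate, ascending flat index among ties
        order = np.lexsort((flat_idx, -rates))
        chosen = flat_idx[order[:k]]
        member.ravel()[chosen] = True
    else:
        raise ValueError(f"unknown place-field mode {mode!r}")
    return PlaceField(member=member, definition_mode=mode)
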