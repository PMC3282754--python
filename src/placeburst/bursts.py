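"""Complex-spike burst detection and the temporal-statistic battery.

A burst is a run of two or more spikes in which every spike occurs within
15 ms of its predecessor with progressively (strictly) decreasing amplitudes.
Detection is a greedy left-to-right scan: the current candidate is extended
while the next inter-spike interval is <= ``max_isi_ms`` and (when amplitude
enforcement is on) the next amplitude is strictly below the current one; a
violating spike terminates the candidate (emitted if it has >= 2 spikes) and
starts a new candidate.  Amplitude ties terminate a burst.  Each spike belongs
to at most one burst.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import PositionTrack, SpikeTrain
from .maps import PlaceField, RateMap, compute_rate_map

MAX_ISI_MS = 15.0

# Histogram conventions (the burst literature states none): intra-burst ISI
# histograms use 0.5-ms bins on (0, 15] ms; whole-session ISI histograms use
# 1-ms bins on (0, 500] ms with the peak searched on (1, 50] ms so the mode
# reflects the burst-scale peak rather than the refractory edge or slow tail.
INTRA_BIN_MS = 0.5
INTRA_RANGE_MS = (0.0, 15.0)
SESSION_BIN_MS = 1.0
SESSION_RANGE_MS = (0.0, 500.0)
SESSION_PEAK_RANGE_MS = (1.0, 50.0)


@dataclass
class Burst:
    """One detected burst: member spike indices (consecutive) and its ISIs."""

    spike_indices: np.ndarray
    isis_ms: np.ndarray
    start_time: float
    end_time: float

    @property
    def n_spikes(self) -> int:
        return len(self.spike_indices)


@dataclass
class ISIStats:
    """Histogram-based and raw statistics of a set of intervals (ms)."""

    peak_time: float  # center of the modal histogram bin, ms
    cv: float  # SD/mean of the raw intervals
    entropy: float  # Shannon entropy of the histogram, bits
    sd: float  # SD of the raw intervals, ms
    n: int = 0


@dataclass
class BurstMetrics:
    """Session-level burst statistics.  ``None`` marks an undefined value."""

    burst_frequency: float  # bursts/s
    intra_burst_spike_rate: float  # spikes-in-bursts per second
    mean_spikes_per_burst: float | None
    intra_burst_ratio: float  # percent of all spikes that are in bursts
    mean_inter_burst_interval: float | None  # s, end-of-burst to next start
    n_bursts: int = 0
    isi_k_stats: dict = field(default_factory=dict)  # k -> ISIStats
    reliability_above_mean: float | None = None
    reliability_top_quartile: float | None = None
    burst_map_coherence_r: float | None = None
    burst_map_coherence_z: float | None = None


def detect_bursts(
    spikes: SpikeTrain, max_isi_ms: float = MAX_ISI_MS, enforce_amplitude: bool = True
) -> list[Burst]:
    """Greedy scan for diminishing-amplitude bursts (see module docstring)."""
    n = len(spikes)
    bursts: list[Burst] = []
    if n < 2:
        return bursts
    t = spikes.times
    amp = spikes.amplitudes
    start = 0
    for i in range(1, n + 1):
        ok = False
        if i < n:
            isi_ms = (t[i] - t[i - 1]) * 1000.0
            ok = isi_ms <= max_isi_ms and (not enforce_amplitude or amp[i] < amp[i - 1])
        if not ok:
            if i - start >= 2:
                idx = np.arange(start, i)
                bursts.append(
                    Burst(
                        spike_indices=idx,
                        isis_ms=np.diff(t[idx]) * 1000.0,
                        start_time=float(t[start]),
                        end_time=float(t[i - 1]),
                    )
                )
            start = i
    return bursts


def burst_spike_indices(bursts: list[Burst]) -> np.ndarray:
    """Sorted indices of all spikes that belong to some burst."""
    if not bursts:
        return np.array([], dtype=int)
    return np.concatenate([b.spike_indices for b in bursts])


def burst_metrics(bursts: list[Burst], spikes: SpikeTrain, duration: float) -> BurstMetrics:
    """Rate/ratio/interval statistics of a session's bursts.

    The inter-burst interval is measured from each burst's end to the next
    burst's start and is undefined (None) with fewer than two bursts.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n_bursts = len(bursts)
    n_burst_spikes = sum(b.n_spikes for b in bursts)
    total = len(spikes)
    metrics = BurstMetrics(
        burst_frequency=n_bursts / duration,
        intra_burst_spike_rate=n_burst_spikes / duration,
        mean_spikes_per_burst=(n_burst_spikes / n_bursts) if n_bursts else None,
        intra_burst_ratio=(100.0 * n_burst_spikes / total) if total else 0.0,
        mean_inter_burst_interval=None,
        n_bursts=n_bursts,
    )
    if n_bursts >= 2:
        gaps = [bursts[i + 1].start_time - bursts[i].end_time for i in range(n_bursts - 1)]
        metrics.mean_inter_burst_interval = float(np.mean(gaps))
    return metrics


def isi_statistics(
    intervals_ms: np.ndarray,
    bin_width_ms: float = INTRA_BIN_MS,
    range_ms: tuple[float, float] = INTRA_RANGE_MS,
    peak_range_ms: tuple[float, float] | None = None,
) -> ISIStats:
    """Peak time, CV, entropy, and SD of a set of intervals.

    The histogram has fixed-width bins on ``range_ms``; the peak is the center
    of the modal bin (ties -> smallest center), optionally restricted to
    ``peak_range_ms``.  Entropy is over nonempty bins of the full histogram.
    CV and SD are computed from the raw intervals, not the histogram.
    """
    x = np.asarray(intervals_ms, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 intervals")
    lo, hi = range_ms
    nbins = int(round((hi - lo) / bin_width_ms))
    counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    if peak_range_ms is not None:
        plo, phi = peak_range_ms
        mask = (centers > plo) & (centers <= phi)
    else:
        mask = np.ones(nbins, dtype=bool)
    if counts[mask].sum() == 0:
        peak = math.nan
    else:
        sub = np.where(mask, counts, -1)
        peak = float(centers[int(np.argmax(sub))])
    total = counts.sum()
    if total == 0:
        entropy = math.nan
    else:
        p = counts[counts > 0] / total
        entropy = float(-np.sum(p * np.log2(p)))
    mean = float(x.mean())
    sd = float(x.std(ddof=0))
    cv = sd / mean if mean > 0 else math.nan
    return ISIStats(peak_time=peak, cv=cv, entropy=entropy, sd=sd, n=len(x))


def intra_burst_isi_series(bursts: list[Burst], k: int) -> np.ndarray:
    """The k-th intra-burst ISI (ms) from every burst with >= k+1 spikes.

    ISI-1 is the interval between the first and second spike of a burst,
    ISI-2 between the second and third, and so on; burst order is preserved.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return np.array([b.isis_ms[k - 1] for b in bursts if b.n_spikes >= k + 1])


def burst_pixels(bursts: list[Burst], spikes: SpikeTrain, track: PositionTrack, geometry: RateMap):
    """(i, j) pixel of the animal at each burst's first spike."""
    onsets = np.array([spikes.times[b.spike_indices[0]] for b in bursts])
    bx, by = track.position_at(onsets)
    return geometry.pixel_index(bx, by)


def burst_reliability(
    bursts: list[Burst],
    spikes: SpikeTrain,
    track: PositionTrack,
    pfield: PlaceField,
    geometry: RateMap,
) -> float:
    """Fraction of bursts whose onset position lies inside the place field.

    Each burst is located at the pixel of the temporally nearest track sample
    at its first spike.
    """
    if not bursts:
        raise ValueError("no bursts to locate")
    bi, bj = burst_pixels(bursts, spikes, track, geometry)
    return float(np.mean(pfield.contains(bi, bj)))


def burst_place_map(
    bursts: list[Burst],
    spikes: SpikeTrain,
    track: PositionTrack,
    arena_radius: float,
    pixel_size: float = 1.0,
    min_occupancy: float = 0.1,
) -> RateMap:
    """Occupancy-normalized map of burst onsets (bursts/s per pixel)."""
    onsets = np.array([spikes.times[b.spike_indices[0]] for b in bursts])
    amps = np.ones_like(onsets)
    onset_train = SpikeTrain(onsets, amps) if len(onsets) else SpikeTrain(np.array([]), np.array([]))
    return compute_rate_map(onset_train, track, arena_radius, pixel_size, min_occupancy)


def burst_table(bursts: list[Burst], spikes: SpikeTrain, track: PositionTrack, geometry: RateMap, pfield: PlaceField):
    """Per-burst export table (one dict per burst)."""
    if not bursts:
        return []
    bi, bj = burst_pixels(bursts, spikes, track, geometry)
    rows = []
    for b, i, j in zip(bursts, bi, bj):
        rows.append(
            {
                "burst_id": len(rows),
                "start_time_s": b.start_time,
                "n_spikes": b.n_spikes,
                "isi1_ms": float(b.isis_ms[0]) if b.n_spikes >= 2 else math.nan,
                "isi2_ms": float(b.isis_ms[1]) if b.n_spikes >= 3 else math.nan,
                "isi3_ms": float(b.isis_ms[2]) if b.n_spikes >= 4 else math.nan,
                "pixel_i": int(i),
                "pixel_j": int(j),
                "in_field": bool(pfield.member[i, j]),
            }
        )
    return rows
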