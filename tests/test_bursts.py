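"""Burst detection, temporal statistics, and burst reliability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placeburst.bursts import (
    burst_metrics,
    burst_place_map,
    burst_reliability,
    burst_spike_indices,
    detect_bursts,
    intra_burst_isi_series,
    isi_statistics,
)
from placeburst.io import PositionTrack, SpikeTrain
from placeburst.maps import PlaceField, compute_rate_map, define_place_field


def train(times_ms, amps):
    return SpikeTrain(np.asarray(times_ms) / 1000.0, np.asarray(amps, dtype=float))


def oracle_bursts(spikes: SpikeTrain, max_isi_ms=15.0, enforce_amplitude=True):
    """Independent maximal-run oracle: link i -> i+1 when the pair predicate
    holds; bursts are maximal runs of linked spikes with >= 2 members."""
    t, a = spikes.times, spikes.amplitudes
    n = len(t)
    if n < 2:
        return []
    link = (np.diff(t) * 1000.0 <= max_isi_ms)
    if enforce_amplitude:
        link &= a[1:] < a[:-1]
    runs = []
    i = 0
    while i < n - 1:
        if link[i]:
            j = i
            while j < n - 1 and link[j]:
                j += 1
            runs.append(list(range(i, j + 1)))
            i = j + 1
        else:
            i += 1
    return runs


def test_hand_traced_scan():
    """times [0,5,12,40,100,101] ms, amps [100,80,60,90,50,45]:
    bursts {0,1,2} and {4,5}; spike 3 is a single."""
    bursts = detect_bursts(train([0, 5, 12, 40, 100, 101], [100, 80, 60, 90, 50, 45]))
    assert [list(b.spike_indices) for b in bursts] == [[0, 1, 2], [4, 5]]
    np.testing.assert_allclose(bursts[0].isis_ms, [5.0, 7.0])


def test_single_spike_no_burst():
    assert detect_bursts(train([10], [50])) == []
    assert detect_bursts(SpikeTrain(np.array([]), np.array([]))) == []


def test_amplitude_enforcement_toggle():
    pair = train([0, 8], [50, 60])
    assert detect_bursts(pair, enforce_amplitude=True) == []
    assert len(detect_bursts(pair, enforce_amplitude=False)) == 1


def test_amplitude_tie_terminates_burst():
    assert detect_bursts(train([0, 8], [50, 50])) == []


@given(st.integers(0, 10_000))
@settings(max_examples=200, deadline=None)
def test_detector_matches_maximal_run_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 120))
    times = np.cumsum(rng.exponential(1.0 / rng.uniform(0.5, 5.0), n)) * 1000  # ms
    amps = rng.uniform(10, 100, n)
    spikes = SpikeTrain(times / 1000.0, amps)
    enforce = bool(rng.integers(0, 2))
    got = [list(b.spike_indices) for b in detect_bursts(spikes, enforce_amplitude=enforce)]
    assert got == oracle_bursts(spikes, enforce_amplitude=enforce)


def test_partition_conservation_and_isi_bound(place_cell_session):
    spikes, _, _ = place_cell_session
    bursts = detect_bursts(spikes)
    in_burst = burst_spike_indices(bursts)
    assert len(set(in_burst.tolist())) == len(in_burst)  # each spike in <= 1 burst
    for b in bursts:
        assert np.all(b.isis_ms <= 15.0)
        assert np.all(np.diff(spikes.amplitudes[b.spike_indices]) < 0)


def test_detection_invariant_to_far_spikes():
    base = train([0, 5, 12], [100, 80, 60])
    with_far = train([0, 5, 12, 500, 1000], [100, 80, 60, 90, 120])
    got_base = [list(b.spike_indices) for b in detect_bursts(base)]
    got_far = [list(b.spike_indices) for b in detect_bursts(with_far)]
    assert got_base == got_far == [[0, 1, 2]]


def test_burst_metrics_arithmetic():
    """3 two-spike bursts among 10 spikes in 30 s: 0.1 Hz bursts, 0.2 Hz
    intra-burst spikes, 60% intra-burst ratio."""
    times = [0, 5, 3000, 3005, 9000, 9005, 15000, 16000, 17000, 18000]
    amps = [100, 80, 100, 80, 100, 80, 50, 50, 50, 50]
    spikes = train(times, amps)
    bursts = detect_bursts(spikes)
    assert len(bursts) == 3
    m = burst_metrics(bursts, spikes, duration=30.0)
    assert m.burst_frequency == pytest.approx(0.1)
    assert m.intra_burst_spike_rate == pytest.approx(0.2)
    assert m.intra_burst_ratio == pytest.approx(60.0)
    assert m.mean_spikes_per_burst == pytest.approx(2.0)


def test_inter_burst_interval_end_to_start():
    spikes = train([9995, 10000, 40000, 40005], [100, 80, 100, 80])
    m = burst_metrics(detect_bursts(spikes), spikes, duration=60.0)
    assert m.mean_inter_burst_interval == pytest.approx(30.0)


def test_no_bursts_missing_fields():
    spikes = train([0, 1000, 2000], [50, 50, 50])
    m = burst_metrics(detect_bursts(spikes), spikes, duration=10.0)
    assert m.burst_frequency == 0.0
    assert m.intra_burst_ratio == 0.0
    assert m.mean_spikes_per_burst is None
    assert m.mean_inter_burst_interval is None


def test_isi_entropy_uniform_bins():
    """Uniform counts over 8 bins give H = 3 bits."""
    intervals = np.arange(8) + 0.5  # one per 1-ms bin of (0, 8]
    s = isi_statistics(intervals, bin_width_ms=1.0, range_ms=(0.0, 8.0))
    assert s.entropy == pytest.approx(3.0)


def test_isi_entropy_weighted_bins():
    """Counts (1,1,2) over 3 bins: H = 1.5 bits."""
    s = isi_statistics(np.array([0.2, 1.2, 2.2, 2.4]), bin_width_ms=1.0, range_ms=(0.0, 3.0))
    assert s.entropy == pytest.approx(1.5)
    assert s.peak_time == pytest.approx(2.5)


def test_isi_constant_intervals():
    s = isi_statistics(np.full(10, 4.0), bin_width_ms=0.5, range_ms=(0.0, 15.0))
    assert s.cv == 0.0
    assert s.entropy == 0.0
    assert s.sd == 0.0


def test_isi_peak_range_restriction():
    """A large refractory-edge bin outside the peak window is ignored."""
    intervals = np.concatenate([np.full(50, 0.4), np.full(10, 5.2)])
    s = isi_statistics(intervals, bin_width_ms=1.0, range_ms=(0.0, 500.0), peak_range_ms=(1.0, 50.0))
    assert s.peak_time == pytest.approx(5.5)


def test_intra_burst_isi_series_sizes():
    spikes = train([0, 5, 100, 105, 111], [100, 80, 100, 80, 60])
    bursts = detect_bursts(spikes)  # sizes (2, 3)
    assert len(intra_burst_isi_series(bursts, 1)) == 2
    assert len(intra_burst_isi_series(bursts, 2)) == 1
    assert len(intra_burst_isi_series(bursts, 3)) == 0


def stationary_track(duration=40.0):
    t = np.arange(int(duration * 60)) / 60.0
    # four quarters at four positions
    x = np.where(t < duration / 2, 2.5, -2.5)
    y = np.zeros_like(t)
    return PositionTrack(t, x, y)


def test_burst_reliability_fractions():
    track = stationary_track()
    # bursts at t=5,10,15 (x=2.5) and t=30 (x=-2.5)
    times, amps = [], []
    for onset in [5.0, 10.0, 15.0, 30.0]:
        times += [onset, onset + 0.005]
        amps += [100, 80]
    spikes = SpikeTrain(np.array(times), np.array(amps, dtype=float))
    bursts = detect_bursts(spikes)
    rm = compute_rate_map(spikes, track, 15.0)
    in_member = np.zeros_like(rm.valid)
    i, j = rm.pixel_index(np.array([2.5]), np.array([0.0]))
    in_member[i[0], j[0]] = True
    field = PlaceField(member=in_member, definition_mode="above_mean")
    assert burst_reliability(bursts, spikes, track, field, rm) == pytest.approx(0.75)
    none_field = PlaceField(member=np.zeros_like(rm.valid), definition_mode="above_mean")
    assert burst_reliability(bursts, spikes, track, none_field, rm) == 0.0
    all_field = PlaceField(member=rm.valid.copy(), definition_mode="above_mean")
    assert burst_reliability(bursts, spikes, track, all_field, rm) == 1.0


def test_burst_place_map_rate():
    """One burst onset in a pixel occupied 2 s maps to 0.5 bursts/s."""
    t = np.arange(120) / 60.0
    track = PositionTrack(t, np.full(120, 0.5), np.full(120, 0.5))
    spikes = SpikeTrain(np.array([1.0, 1.005]), np.array([100.0, 80.0]))
    bursts = detect_bursts(spikes)
    bmap = burst_place_map(bursts, spikes, track, 15.0)
    i, j = bmap.pixel_index(np.array([0.5]), np.array([0.5]))
    assert bmap.rate[i[0], j[0]] == pytest.approx(0.5, rel=0.02)


def test_burst_map_field_overlaps_spike_map_field(place_cell_session):
    """The burst place-map peaks where the spike map does (same place field)."""
    spikes, track, params = place_cell_session
    bursts = detect_bursts(spikes)
    rm = compute_rate_map(spikes, track, 15.0)
    bmap = burst_place_map(bursts, spikes, track, 15.0)

    def centroid(m):
        cx, cy = m.centers()
        w = np.where(m.valid, m.rate, 0.0)
        return np.sum(cx * w) / w.sum(), np.sum(cy * w) / w.sum()

    sx, sy = centroid(rm)
    bx, by = centroid(bmap)
    assert np.hypot(sx - bx, sy - by) < params.field_width
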