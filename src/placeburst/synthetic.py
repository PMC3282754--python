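"""Synthetic recordings: foraging trajectories and bursty place-tuned spiking.

The generator emulates the recording conditions the analysis battery assumes:
random foraging at ~6.2 cm/s in a 30-cm-diameter cylinder sampled at 60 Hz for
25-min sessions, and place cells whose firing events follow an inhomogeneous
Poisson process with Gaussian spatial tuning.  Generation is doubly
stochastic — events first, then single-spike-or-burst composition — so the
burst-level statistics under test (spikes per burst, intra-burst ISI mean and
dispersion) are directly controllable.  Intra-burst ISIs are gamma-distributed
with a configurable mean and shape, truncated by rejection to (0, 15) ms so
generated bursts satisfy the detector's definition; amplitudes decay by a
fixed fraction per spike within a burst, making them strictly decreasing.

Three-session cue-rotation protocols are supported: a distal-following cell
keeps its field; a local-following cell's field rotates with the cue card; a
remap cell's field is redrawn at a genuinely different angular position (the
redraw is rejection-sampled to be at least 60 degrees, direction-folded, from
both the original position and the card-rotated position, which is what
"remapped" means operationally under a cue-rotation protocol).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace

import numpy as np

from .io import PositionTrack, SessionDescriptor, SpikeTrain

REMAP_MIN_SEPARATION_DEG = 60.0


@dataclass
class TrajectoryParams:
    """Random-foraging trajectory parameters (study conditions as defaults)."""

    mean_speed: float = 6.2  # cm/s, matches observed foraging speeds
    heading_persistence: float = 0.7  # s, heading decorrelation time
    sample_rate: float = 60.0  # Hz, overhead camera refresh
    arena_radius: float = 15.0  # cm (30-cm-diameter cylinder)
    duration: float = 1500.0  # s (25-min session)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_speed <= 0 or self.sample_rate <= 0:
            raise ValueError("mean_speed and sample_rate must be positive")
        if self.arena_radius <= 0 or self.duration <= 0:
            raise ValueError("arena_radius and duration must be positive")


@dataclass
class SyntheticCellParams:
    """Generative parameters of one synthetic place cell."""

    field_center: tuple[float, float] = (7.0, 0.0)  # cm
    field_width: float = 4.0  # cm, Gaussian sd of the tuning curve
    peak_event_rate: float = 5.0  # Hz, firing-event rate at the field center
    baseline_event_rate: float = 0.1  # Hz, out-of-field event rate
    p_single: float = 0.8  # probability a firing event is a lone spike
    burst_continue: float = 0.18  # geometric tail: P(one more spike | >= 2)
    intra_isi_mean: float = 2.5  # ms, mean intra-burst ISI
    intra_isi_shape: float = 3.0  # gamma shape (dispersion control)
    amp0: float = 100.0  # arbitrary units, first-spike amplitude
    amp_decay: float = 0.3  # fractional amplitude drop per successive spike
    cue_type: str = "distal"  # {distal, local, remap}

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_single <= 1.0):
            raise ValueError("p_single must be in [0, 1]")
        if not (0.0 < self.burst_continue < 1.0):
            raise ValueError("burst_continue must be in (0, 1)")
        if not (0.0 < self.intra_isi_mean < 15.0):
            raise ValueError("intra_isi_mean must be in (0, 15) ms")
        if not (0.0 < self.amp_decay < 1.0):
            raise ValueError("amp_decay must be in (0, 1)")
        if self.cue_type not in ("distal", "local", "remap"):
            raise ValueError(f"unknown cue_type {self.cue_type!r}")


def simulate_trajectory(params: TrajectoryParams) -> PositionTrack:
    """Random foraging: mean-reverting heading and speed, reflective walls.

    Heading follows a Brownian walk whose diffusion is set by
    ``heading_persistence``; speed follows an Ornstein-Uhlenbeck process
    around ``mean_speed`` (sd 20% of the mean).  Steps that would leave the
    arena reflect the heading off the wall; a step that would still land
    outside after reflection is not taken.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(params.seed)
    dt = 1.0 / params.sample_rate
    n = int(round(params.duration * params.sample_rate))
    r_max = params.arena_radius - 1e-9

    heading_noise = rng.standard_normal(n) * math.sqrt(2.0 * dt / params.heading_persistence)
    speed_sd = 0.2 * params.mean_speed
    speed_noise = rng.standard_normal(n) * speed_sd * math.sqrt(2.0 * dt)

    xs = np.empty(n)
    ys = np.empty(n)
    # start at a random interior point
    r0 = 0.5 * params.arena_radius * math.sqrt(rng.uniform())
    a0 = rng.uniform(0.0, 2.0 * math.pi)
    x, y = r0 * math.cos(a0), r0 * math.sin(a0)
    heading = rng.uniform(0.0, 2.0 * math.pi)
    speed = params.mean_speed
    mean_speed = params.mean_speed
    min_speed = 0.05 * mean_speed
    for i in range(n):
        xs[i] = x
        ys[i] = y
        heading += heading_noise[i]
        speed += (mean_speed - speed) * dt + speed_noise[i]
        if speed < min_speed:
            speed = min_speed
        step = speed * dt
        dx, dy = step * math.cos(heading), step * math.sin(heading)
        nx, ny = x + dx, y + dy
        if nx * nx + ny * ny > r_max * r_max:
            # reflect velocity off the wall normal at the current position
            rr = math.hypot(x, y)
            if rr > 0:
                ux, uy = x / rr, y / rr
                dot = dx * ux + dy * uy
                dx, dy = dx - 2.0 * dot * ux, dy - 2.0 * dot * uy
                heading = math.atan2(dy, dx)
                nx, ny = x + dx, y + dy
            if nx * nx + ny * ny > r_max * r_max:
                nx, ny = x, y  # stay put this sample
        x, y = nx, ny
    times = np.arange(n) * dt
    return PositionTrack(times, xs, ys)


def _event_rate(track: PositionTrack, params: SyntheticCellParams) -> np.ndarray:
    cx, cy = params.field_center
    d2 = (track.x - cx) ** 2 + (track.y - cy) ** 2
    return params.baseline_event_rate + params.peak_event_rate * np.exp(
        -d2 / (2.0 * params.field_width**2)
    )


def _truncated_gamma_ms(rng: np.random.Generator, mean: float, shape: float, size: int) -> np.ndarray:
    """Gamma(shape, mean/shape) samples rejected outside (0, 15) ms."""
    out = np.empty(size)
    filled = 0
    scale = mean / shape
    while filled < size:
        draw = rng.gamma(shape, scale, size=2 * (size - filled) + 8)
        good = draw[(draw > 0.0) & (draw < 15.0)]
        take = min(len(good), size - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def simulate_place_cell(track: PositionTrack, params: SyntheticCellParams, seed: int) -> SpikeTrain:
    """Bursty place-tuned spike train along a trajectory.

    Firing events are drawn from an inhomogeneous Poisson process with rate
    baseline + peak * exp(-||pos - center||^2 / (2 width^2)) by thinning a
    homogeneous process at the peak total rate.  Each event is a lone spike
    with probability ``p_single``; otherwise it is a burst whose extra-spike
    count is geometric(``burst_continue``) and whose consecutive ISIs are
    truncated-gamma with mean ``intra_isi_mean``.  Amplitudes within a burst
    decay by a factor (1 - ``amp_decay``) per spike; a lone spike has
    amplitude ``amp0``.
    """
    if len(track) == 0:
        raise ValueError("empty position track")
    rng = np.random.default_rng(seed)
    t0 = float(track.times[0])
    span = float(track.times[-1] - track.times[0])
    lam_max = params.baseline_event_rate + params.peak_event_rate
    if lam_max <= 0 or span <= 0:
        return SpikeTrain(np.array([]), np.array([]))
    n_cand = rng.poisson(lam_max * span)
    # offsets from the track origin keep generation invariant to time origin
    offsets = np.sort(rng.uniform(0.0, span, size=n_cand))
    cand = t0 + offsets
    rates = _event_rate(track, params)
    lam = rates[track.nearest_sample(cand)] if n_cand else np.array([])
    accept = rng.uniform(size=n_cand) < lam / lam_max
    events = cand[accept]

    times: list[float] = []
    amps: list[float] = []
    keep = 1.0 - params.amp_decay
    is_single = rng.uniform(size=len(events)) < params.p_single
    n_extras = rng.geometric(1.0 - params.burst_continue, size=len(events))
    for ev, single, extras in zip(events, is_single, n_extras):
        if single:
            times.append(ev)
            amps.append(params.amp0)
            continue
        isis_s = _truncated_gamma_ms(rng, params.intra_isi_mean, params.intra_isi_shape, int(extras)) / 1000.0
        t = ev
        a = params.amp0
        times.append(t)
        amps.append(a)
        for ds in isis_s:
            t += ds
            a *= keep
            times.append(t)
            amps.append(a)
    if not times:
        return SpikeTrain(np.array([]), np.array([]))
    times_arr = np.asarray(times)
    amps_arr = np.asarray(amps)
    order = np.argsort(times_arr, kind="stable")
    times_arr, amps_arr = times_arr[order], amps_arr[order]
    # enforce strict monotonicity: drop spikes within 0.01 ms of a predecessor
    keep_mask = np.ones(len(times_arr), dtype=bool)
    last = -np.inf
    for i, t in enumerate(times_arr):
        if t - last <= 1e-5:
            keep_mask[i] = False
        else:
            last = t
    # clip to the tracked window
    keep_mask &= times_arr <= track.times[-1]
    keep_mask &= times_arr >= t0
    return SpikeTrain(times_arr[keep_mask], amps_arr[keep_mask])


def apply_cue_protocol(
    params: SyntheticCellParams,
    descriptor: SessionDescriptor,
    seed: int,
    reference_card_angle: float = 0.0,
    arena_radius: float | None = None,
) -> SyntheticCellParams:
    """Session-specific field placement under the cue protocol.

    ``params.field_center`` is the cell's session-1 (reference) field center.
    Rotation is the session's card angle relative to ``reference_card_angle``.
    distal: unchanged.  local: center rotated by the card rotation about the
    arena center.  remap (sessions after the first): center redrawn, seeded,
    uniformly in radius within the arena but constrained in angle to be
    >= 60 degrees (folded) from both the original and the card-rotated
    position.
    """
    rotation = descriptor.card_angle_deg - reference_card_angle
    radius = arena_radius if arena_radius is not None else descriptor.arena_radius_cm
    cx, cy = params.field_center
    if params.cue_type == "distal":
        return params
    if params.cue_type == "local":
        th = math.radians(rotation)
        nx = cx * math.cos(th) - cy * math.sin(th)
        ny = cx * math.sin(th) + cy * math.cos(th)
        return replace(params, field_center=(nx, ny))
    # remap
    if descriptor.session_id == 1:
        return params
    rng = np.random.default_rng(seed)
    base_angle = math.degrees(math.atan2(cy, cx))
    r_lo, r_hi = 0.2 * radius, 0.7 * radius

    def folded(a: float) -> float:
        a = a % 360.0
        return min(a, 360.0 - a)

    for _ in range(1000):
        ang = rng.uniform(0.0, 360.0)
        if (
            folded(ang - base_angle) >= REMAP_MIN_SEPARATION_DEG
            and folded(ang - base_angle - rotation) >= REMAP_MIN_SEPARATION_DEG
        ):
            break
    rr = math.sqrt(rng.uniform(r_lo**2, r_hi**2))
    th = math.radians(ang)
    return replace(params, field_center=(rr * math.cos(th), rr * math.sin(th)))


def default_protocol(
    arena_radius: float = 15.0, duration: float = 1500.0, card_rotation: float = 90.0
) -> list[SessionDescriptor]:
    """The three-session protocol: identical cues in sessions 1 and 3, card
    rotated CCW by ``card_rotation`` degrees in session 2."""
    return [
        SessionDescriptor(1, arena_radius, 0.0, duration),
        SessionDescriptor(2, arena_radius, card_rotation % 360.0, duration),
        SessionDescriptor(3, arena_radius, 0.0, duration),
    ]


@dataclass
class CohortParams:
    """Group-level generator settings for a cohort of synthetic cells.

    Per-cell parameters are drawn around the ``cell`` template: field centers
    uniformly at radius ``field_center_radius`` (angle uniform), peak event
    rates and intra-burst ISI means jittered by the given fractions.
    """

    cell: SyntheticCellParams = dataclasses.field(default_factory=SyntheticCellParams)
    trajectory: TrajectoryParams = dataclasses.field(default_factory=TrajectoryParams)
    field_center_radius: tuple[float, float] = (3.0, 10.0)  # cm
    peak_rate_jitter: float = 0.2  # fractional, uniform
    isi_mean_jitter: float = 0.1  # fractional, uniform


def _draw_cell_params(base: CohortParams, rng: np.random.Generator, cue_type: str) -> SyntheticCellParams:
    r_lo, r_hi = base.field_center_radius
    rr = math.sqrt(rng.uniform(r_lo**2, r_hi**2))
    ang = rng.uniform(0.0, 2.0 * math.pi)
    peak = base.cell.peak_event_rate * rng.uniform(1.0 - base.peak_rate_jitter, 1.0 + base.peak_rate_jitter)
    isi_mean = base.cell.intra_isi_mean * rng.uniform(1.0 - base.isi_mean_jitter, 1.0 + base.isi_mean_jitter)
    return replace(
        base.cell,
        field_center=(rr * math.cos(ang), rr * math.sin(ang)),
        peak_event_rate=peak,
        intra_isi_mean=min(isi_mean, 14.9),
        cue_type=cue_type,
    )


def generate_cohort(
    n_cells: int,
    group_params: CohortParams,
    protocol: list[SessionDescriptor] | None = None,
    master_seed: int = 0,
    cue_types: list[str] | None = None,
) -> list[list[tuple[SpikeTrain, PositionTrack, SessionDescriptor]]]:
    """Cohort of cells, each recorded over the 3-session protocol.

    Returns, per cell, a list of (SpikeTrain, PositionTrack, SessionDescriptor)
    per session.  Trajectories are independent across sessions; everything is
    reproducible from ``master_seed``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if protocol is None:
        protocol = default_protocol(
            arena_radius=group_params.trajectory.arena_radius,
            duration=group_params.trajectory.duration,
        )
    if cue_types is None:
        cue_types = [group_params.cell.cue_type] * n_cells
    if len(cue_types) != n_cells:
        raise ValueError("cue_types must have length n_cells")
    ref_card = protocol[0].card_angle_deg
    ss = np.random.SeedSequence(master_seed)
    cell_seeds = ss.spawn(n_cells)
    cohort = []
    for c in range(n_cells):
        sub = cell_seeds[c].spawn(2 * len(protocol) + 1)
        draw_rng = np.random.default_rng(sub[0])
        base_params = _draw_cell_params(group_params, draw_rng, cue_types[c])
        sessions = []
        for s, desc in enumerate(protocol):
            traj_seed = int(sub[1 + 2 * s].generate_state(1)[0] % (2**31))
            spike_seed = int(sub[2 + 2 * s].generate_state(1)[0] % (2**31))
            traj = simulate_trajectory(
                replace(
                    group_params.trajectory,
                    arena_radius=desc.arena_radius_cm,
                    duration=desc.duration_s,
                    seed=traj_seed,
                )
            )
            cell_for_session = apply_cue_protocol(
                base_params, desc, seed=spike_seed, reference_card_angle=ref_card
            )
            spikes = simulate_place_cell(traj, cell_for_session, seed=spike_seed)
            sessions.append((spikes, traj, desc))
        cohort.append(sessions)
    return cohort
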