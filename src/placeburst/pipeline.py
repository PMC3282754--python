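"""Per-cell / per-session orchestration, inclusion filter, group comparisons.

``analyze_cell`` runs the full battery on one cell's three sessions: rate map,
place fields (above-mean and top-quartile), spatial selectivity / coherence /
information, burst detection with the temporal statistics, burst reliability,
the cross-validated spatial regression, pairwise cross-session similarity with
rotation search and cue classification, and the pooled (all-sessions-combined)
temporal statistics.  ``compare_groups`` applies a two-tailed Welch t-test per
metric; a Benjamini-Hochberg column is emitted alongside for transparency but
is not used for any decision, since the per-metric tests are reported
uncorrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import bursts as burst_mod
from .exceptions import DegenerateOverlapError, EmptyFieldError, UndefinedCoherenceError
from .io import PositionTrack, SessionDescriptor, SpikeTrain
from .maps import DEFAULT_MIN_OCCUPANCY, RateMap, compute_rate_map, define_place_field
from .models import DEFAULT_SPAN_GRID, SpatialRateRegression
from .spatial_metrics import (
    in_out_field_rates,
    occupancy_weighted_rate,
    spatial_coherence,
    spatial_information,
    spatial_selectivity,
)
from .stability import best_rotation, classify_cue_following, map_similarity

logger = logging.getLogger(__name__)

NAN = math.nan


@dataclass
class AnalysisConfig:
    """Every analysis default in one place (all are overridable)."""

    pixel_size: float = 1.0  # cm
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY  # s
    max_isi_ms: float = 15.0
    enforce_amplitude: bool = True
    intra_bin_ms: float = burst_mod.INTRA_BIN_MS
    intra_range_ms: tuple[float, float] = burst_mod.INTRA_RANGE_MS
    session_bin_ms: float = burst_mod.SESSION_BIN_MS
    session_range_ms: tuple[float, float] = burst_mod.SESSION_RANGE_MS
    session_peak_range_ms: tuple[float, float] = burst_mod.SESSION_PEAK_RANGE_MS
    span_grid: tuple[float, ...] = DEFAULT_SPAN_GRID
    cv_k: int = 10
    rotation_step: float = 1.0
    inclusion_session: int = 1  # session whose map gates cell inclusion
    min_rate_hz: float = 0.2
    min_selectivity: float = 0.5
    fit_regression: bool = True
    seed: int = 0


@dataclass
class CellSessionMetrics:
    """Flat per-cell-session record (session_id 0 = all sessions combined)."""

    cell_id: str
    session_id: int
    group: str
    included: bool = True
    duration_s: float = NAN
    n_spikes: int = 0
    overall_rate: float = NAN  # spikes / session duration, Hz
    map_mean_rate: float = NAN  # occupancy-weighted map mean, Hz
    in_field_rate: float = NAN
    out_field_rate: float = NAN
    selectivity: float = NAN
    burst_selectivity: float = NAN  # selectivity from burst spikes only
    coherence_r: float = NAN
    coherence_z: float = NAN
    information_rate: float = NAN
    field_size_above_mean: float = NAN
    field_size_top_quartile: float = NAN
    burst_frequency: float = NAN
    intra_burst_spike_rate: float = NAN
    mean_spikes_per_burst: float = NAN
    intra_burst_ratio: float = NAN
    mean_inter_burst_interval: float = NAN
    n_bursts: int = 0
    isi1_mean_ms: float = NAN
    isi1_peak_ms: float = NAN
    isi1_entropy_bits: float = NAN
    isi1_cv: float = NAN
    isi1_sd_ms: float = NAN
    isi2_mean_ms: float = NAN
    isi2_entropy_bits: float = NAN
    isi3_mean_ms: float = NAN
    isi3_entropy_bits: float = NAN
    session_isi_peak_ms: float = NAN
    session_isi_cv: float = NAN
    session_isi_entropy_bits: float = NAN
    session_isi_sd_ms: float = NAN
    reliability_above_mean: float = NAN
    reliability_top_quartile: float = NAN
    burst_map_coherence_r: float = NAN
    burst_map_coherence_z: float = NAN
    regression_span: float = NAN
    regression_pve: float = NAN


METRICS_FIELDNAMES = [f.name for f in fields(CellSessionMetrics)]


@dataclass
class PairStability:
    """Cross-session similarity / rotation record for one session pair."""

    cell_id: str
    group: str
    pair: str  # e.g. "1v2"
    session_a: int
    session_b: int
    card_rotation: float  # deg CCW, session_b card relative to session_a
    r: float = NAN
    z: float = NAN
    n_pixels: int = 0
    best_angle: float = NAN
    abs_rotation: float = NAN
    max_r: float = NAN
    max_z: float = NAN
    cue_class: str = ""


@dataclass
class GroupComparison:
    """Welch two-sample comparison of one metric between groups."""

    metric: str
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    t: float
    df: float
    p: float
    p_bh: float = NAN


def include_cell(mean_rate: float, selectivity: float, min_rate: float = 0.2, min_selectivity: float = 0.5) -> bool:
    """Place-cell inclusion rule: mean rate > 0.2 Hz AND selectivity > 0.5.

    Both inequalities are strict.
    """
    return bool(mean_rate > min_rate and selectivity > min_selectivity)


def _isi_stats_or_nan(intervals: np.ndarray, **kwargs) -> burst_mod.ISIStats:
    if len(intervals) >= 2:
        return burst_mod.isi_statistics(intervals, **kwargs)
    return burst_mod.ISIStats(NAN, NAN, NAN, NAN, n=len(intervals))


def _analyze_one_session(
    spikes: SpikeTrain,
    track: PositionTrack,
    desc: SessionDescriptor,
    cfg: AnalysisConfig,
    rec: CellSessionMetrics,
) -> RateMap | None:
    """Fill ``rec`` in place; returns the rate map (None when degenerate)."""
    rec.duration_s = desc.duration_s
    rec.n_spikes = len(spikes)
    rec.overall_rate = len(spikes) / desc.duration_s

    rm = compute_rate_map(spikes, track, desc.arena_radius_cm, cfg.pixel_size, cfg.min_occupancy)
    try:
        rec.map_mean_rate = occupancy_weighted_rate(rm)
    except EmptyFieldError:
        return None
    try:
        pf = define_place_field(rm, "above_mean")
        pf_top = define_place_field(rm, "top_quartile")
        rec.field_size_above_mean = pf.size
        rec.field_size_top_quartile = pf_top.size
        rec.in_field_rate, rec.out_field_rate = in_out_field_rates(rm, pf)
        rec.selectivity = spatial_selectivity(rm, pf)
    except EmptyFieldError:
        pf = pf_top = None
    try:
        rec.coherence_r, rec.coherence_z = spatial_coherence(rm)
    except UndefinedCoherenceError:
        pass
    try:
        rec.information_rate = spatial_information(rm)
    except (ValueError, EmptyFieldError):
        pass

    # bursts and temporal statistics
    blist = burst_mod.detect_bursts(spikes, cfg.max_isi_ms, cfg.enforce_amplitude)
    bm = burst_mod.burst_metrics(blist, spikes, desc.duration_s)
    rec.n_bursts = bm.n_bursts
    rec.burst_frequency = bm.burst_frequency
    rec.intra_burst_spike_rate = bm.intra_burst_spike_rate
    rec.mean_spikes_per_burst = bm.mean_spikes_per_burst if bm.mean_spikes_per_burst is not None else NAN
    rec.intra_burst_ratio = bm.intra_burst_ratio
    rec.mean_inter_burst_interval = (
        bm.mean_inter_burst_interval if bm.mean_inter_burst_interval is not None else NAN
    )
    intra_kwargs = dict(bin_width_ms=cfg.intra_bin_ms, range_ms=cfg.intra_range_ms)
    s1 = _isi_stats_or_nan(burst_mod.intra_burst_isi_series(blist, 1), **intra_kwargs)
    s2 = _isi_stats_or_nan(burst_mod.intra_burst_isi_series(blist, 2), **intra_kwargs)
    s3 = _isi_stats_or_nan(burst_mod.intra_burst_isi_series(blist, 3), **intra_kwargs)
    isi1 = burst_mod.intra_burst_isi_series(blist, 1)
    rec.isi1_mean_ms = float(np.mean(isi1)) if len(isi1) else NAN
    rec.isi1_peak_ms, rec.isi1_entropy_bits = s1.peak_time, s1.entropy
    rec.isi1_cv, rec.isi1_sd_ms = s1.cv, s1.sd
    isi2 = burst_mod.intra_burst_isi_series(blist, 2)
    rec.isi2_mean_ms = float(np.mean(isi2)) if len(isi2) else NAN
    rec.isi2_entropy_bits = s2.entropy
    isi3 = burst_mod.intra_burst_isi_series(blist, 3)
    rec.isi3_mean_ms = float(np.mean(isi3)) if len(isi3) else NAN
    rec.isi3_entropy_bits = s3.entropy

    sess = _isi_stats_or_nan(
        spikes.isis_ms(),
        bin_width_ms=cfg.session_bin_ms,
        range_ms=cfg.session_range_ms,
        peak_range_ms=cfg.session_peak_range_ms,
    )
    rec.session_isi_peak_ms = sess.peak_time
    rec.session_isi_cv = sess.cv
    rec.session_isi_entropy_bits = sess.entropy
    rec.session_isi_sd_ms = sess.sd

    # burst reliability and the burst place-map
    if blist and pf is not None:
        rec.reliability_above_mean = burst_mod.burst_reliability(blist, spikes, track, pf, rm)
        rec.reliability_top_quartile = burst_mod.burst_reliability(blist, spikes, track, pf_top, rm)
        bmap = burst_mod.burst_place_map(
            blist, spikes, track, desc.arena_radius_cm, cfg.pixel_size, cfg.min_occupancy
        )
        try:
            rec.burst_map_coherence_r, rec.burst_map_coherence_z = spatial_coherence(bmap)
        except UndefinedCoherenceError:
            pass
        # selectivity from burst spikes only: burst-restricted train, same rule
        bidx = burst_mod.burst_spike_indices(blist)
        if len(bidx) >= 2:
            btrain = spikes.subset(bidx)
            brm = compute_rate_map(btrain, track, desc.arena_radius_cm, cfg.pixel_size, cfg.min_occupancy)
            try:
                bpf = define_place_field(brm, "above_mean")
                rec.burst_selectivity = spatial_selectivity(brm, bpf)
            except EmptyFieldError:
                pass

    if cfg.fit_regression:
        try:
            model = SpatialRateRegression(rm)
            span = model.select_span(cfg.span_grid, k=cfg.cv_k, seed=cfg.seed)
            res = model.fit(span)
            rec.regression_span = span
            rec.regression_pve = res.pve
        except ValueError:
            pass
    return rm


def _concatenate_sessions(
    sessions: list[tuple[SpikeTrain, PositionTrack, SessionDescriptor]],
) -> tuple[SpikeTrain, float]:
    """Spikes from all sessions on a common time axis, plus total duration."""
    times, amps = [], []
    offset = 0.0
    for spikes, _track, desc in sessions:
        times.append(spikes.times + offset)
        amps.append(spikes.amplitudes)
        offset += desc.duration_s
    t = np.concatenate(times)
    a = np.concatenate(amps)
    keep = np.ones(len(t), dtype=bool)
    keep[1:] = np.diff(t) > 1e-9
    return SpikeTrain(t[keep], a[keep]), offset


def analyze_cell(
    sessions: list[tuple[SpikeTrain, PositionTrack, SessionDescriptor]],
    config: AnalysisConfig | None = None,
    cell_id: str = "cell",
    group: str = "",
) -> tuple[list[CellSessionMetrics], list[PairStability]]:
    """Full battery on one cell's sessions (typically three).

    Returns per-session metric records (plus a session_id-0 record holding
    the temporal statistics over all sessions concatenated) and the pairwise
    stability records.  Inclusion is gated on the configured session's mean
    rate and selectivity and recorded on every row.
    """
    cfg = config or AnalysisConfig()
    records: list[CellSessionMetrics] = []
    ratemaps: dict[int, RateMap] = {}
    descs: dict[int, SessionDescriptor] = {}
    for spikes, track, desc in sessions:
        rec = CellSessionMetrics(cell_id=cell_id, session_id=desc.session_id, group=group)
        try:
            rm = _analyze_one_session(spikes, track, desc, cfg, rec)
        except Exception:
            logger.exception("cell %s session %s: analysis failed", cell_id, desc.session_id)
            raise
        if rm is not None:
            ratemaps[desc.session_id] = rm
            descs[desc.session_id] = desc
        records.append(rec)

    # inclusion gate from the configured session
    gate = next((r for r in records if r.session_id == cfg.inclusion_session), None)
    included = bool(
        gate is not None
        and np.isfinite(gate.overall_rate)
        and not math.isnan(gate.selectivity)  # +inf selectivity still passes the > rule
        and include_cell(gate.overall_rate, gate.selectivity, cfg.min_rate_hz, cfg.min_selectivity)
    )
    if not included:
        logger.info("cell %s excluded by the rate/selectivity filter", cell_id)
    for r in records:
        r.included = included

    # pooled temporal statistics over the concatenated sessions
    if len(sessions) > 1:
        combined, total_duration = _concatenate_sessions(sessions)
        comb_desc = SessionDescriptor(
            session_id=sessions[0][2].session_id,
            arena_radius_cm=sessions[0][2].arena_radius_cm,
            card_angle_deg=sessions[0][2].card_angle_deg,
            duration_s=total_duration,
        )
        comb = CellSessionMetrics(cell_id=cell_id, session_id=0, group=group, included=included)
        comb.duration_s = total_duration
        comb.n_spikes = len(combined)
        comb.overall_rate = len(combined) / total_duration
        blist = burst_mod.detect_bursts(combined, cfg.max_isi_ms, cfg.enforce_amplitude)
        bm = burst_mod.burst_metrics(blist, combined, total_duration)
        comb.n_bursts = bm.n_bursts
        comb.burst_frequency = bm.burst_frequency
        comb.intra_burst_spike_rate = bm.intra_burst_spike_rate
        comb.mean_spikes_per_burst = bm.mean_spikes_per_burst if bm.mean_spikes_per_burst is not None else NAN
        comb.intra_burst_ratio = bm.intra_burst_ratio
        comb.mean_inter_burst_interval = (
            bm.mean_inter_burst_interval if bm.mean_inter_burst_interval is not None else NAN
        )
        isi1 = burst_mod.intra_burst_isi_series(blist, 1)
        comb.isi1_mean_ms = float(np.mean(isi1)) if len(isi1) else NAN
        s1 = _isi_stats_or_nan(isi1, bin_width_ms=cfg.intra_bin_ms, range_ms=cfg.intra_range_ms)
        comb.isi1_peak_ms, comb.isi1_entropy_bits = s1.peak_time, s1.entropy
        comb.isi1_cv, comb.isi1_sd_ms = s1.cv, s1.sd
        sess = _isi_stats_or_nan(
            combined.isis_ms(),
            bin_width_ms=cfg.session_bin_ms,
            range_ms=cfg.session_range_ms,
            peak_range_ms=cfg.session_peak_range_ms,
        )
        comb.session_isi_peak_ms = sess.peak_time
        comb.session_isi_cv = sess.cv
        comb.session_isi_entropy_bits = sess.entropy
        comb.session_isi_sd_ms = sess.sd
        records.append(comb)

    # pairwise stability with rotation search and cue classification
    pairs: list[PairStability] = []
    for sa, sb in combinations(sorted(ratemaps), 2):
        card_rot = descs[sb].card_angle_deg - descs[sa].card_angle_deg
        card_rot = (card_rot + 180.0) % 360.0 - 180.0  # fold to (-180, 180]
        if card_rot == -180.0:
            card_rot = 180.0
        pair = PairStability(
            cell_id=cell_id,
            group=group,
            pair=f"{sa}v{sb}",
            session_a=sa,
            session_b=sb,
            card_rotation=card_rot,
        )
        try:
            sim = map_similarity(ratemaps[sa], ratemaps[sb])
            pair.r, pair.z, pair.n_pixels = sim.r, sim.z, sim.n_pixels
            rot = best_rotation(ratemaps[sa], ratemaps[sb], step=cfg.rotation_step)
            pair.best_angle = rot.best_angle
            pair.abs_rotation = rot.abs_rotation
            pair.max_r, pair.max_z = rot.max_r, rot.max_z
            pair.cue_class = classify_cue_following(rot, card_rot).value
        except DegenerateOverlapError:
            logger.info("cell %s pair %s: degenerate overlap, stability skipped", cell_id, pair.pair)
        pairs.append(pair)
    return records, pairs


# default metric set for group comparisons (every quantity the battery reports)
DEFAULT_COMPARISON_METRICS = (
    "overall_rate",
    "in_field_rate",
    "selectivity",
    "burst_selectivity",
    "coherence_z",
    "information_rate",
    "field_size_above_mean",
    "burst_frequency",
    "intra_burst_spike_rate",
    "mean_spikes_per_burst",
    "intra_burst_ratio",
    "mean_inter_burst_interval",
    "isi1_mean_ms",
    "isi1_entropy_bits",
    "isi1_sd_ms",
    "session_isi_peak_ms",
    "session_isi_cv",
    "session_isi_entropy_bits",
    "reliability_above_mean",
    "reliability_top_quartile",
    "burst_map_coherence_z",
    "regression_pve",
)


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(t, Welch-Satterthwaite df, two-tailed p) for two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    denom = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    df = (va / na + vb / nb) ** 2 / denom if denom > 0 else float(na + nb - 2)
    t = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(t):  # both samples constant and equal
        t, p = 0.0, 1.0
    return t, float(df), p


def compare_groups(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_COMPARISON_METRICS,
    min_n: int = 2,
) -> pd.DataFrame:
    """Welch t-test per metric between two per-cell metric tables.

    Missing values are dropped pairwise per metric (per-metric n varies, as
    when the inter-burst interval is undefined for a cell).  Raises when a
    metric has fewer than ``min_n`` finite values in a group.
    """
    rows = []
    for metric in metrics:
        a = table_a[metric].to_numpy(dtype=float)
        b = table_b[metric].to_numpy(dtype=float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if len(a) < min_n or len(b) < min_n:
            raise ValueError(f"metric {metric!r}: fewer than {min_n} finite values in a group")
        t, df, p = welch_ttest(a, b)
        rows.append(
            GroupComparison(
                metric=metric,
                mean_a=float(a.mean()),
                sem_a=float(a.std(ddof=1) / np.sqrt(len(a))),
                n_a=len(a),
                mean_b=float(b.mean()),
                sem_b=float(b.std(ddof=1) / np.sqrt(len(b))),
                n_b=len(b),
                t=t,
                df=df,
                p=p,
            )
        )
    out = pd.DataFrame([vars(r) for r in rows])
    out["p_bh"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


def analyze_cohort(
    cohorts: dict[str, list],
    config: AnalysisConfig | None = None,
    apply_inclusion: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run :func:`analyze_cell` over every cell of every group.

    ``cohorts`` maps a group label to a list of cells, each a list of
    (SpikeTrain, PositionTrack, SessionDescriptor) sessions.  Returns the
    per-cell-session metrics table and the pairwise stability table; when
    ``apply_inclusion`` is set, the tables keep only included cells.
    """
    cfg = config or AnalysisConfig()
    metric_rows: list[CellSessionMetrics] = []
    pair_rows: list[PairStability] = []
    for group, cells in cohorts.items():
        for c, sessions in enumerate(cells):
            cell_id = f"{group}-{c:03d}"
            recs, pairs = analyze_cell(sessions, cfg, cell_id=cell_id, group=group)
            metric_rows.extend(recs)
            if recs and recs[0].included:
                pair_rows.extend(pairs)
            elif not apply_inclusion:
                pair_rows.extend(pairs)
    metrics_df = pd.DataFrame([vars(r) for r in metric_rows], columns=METRICS_FIELDNAMES)
    pairs_df = pd.DataFrame(
        [vars(p) for p in pair_rows],
        columns=[f.name for f in fields(PairStability)],
    )
    if apply_inclusion and len(metrics_df):
        metrics_df = metrics_df[metrics_df["included"]].reset_index(drop=True)
    return metrics_df, pairs_df
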