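"""Scalar spatial statistics of a rate map.

* Spatial selectivity: log10 of in-field over out-field mean firing rate.
* Spatial coherence: Pearson correlation between each valid pixel's rate and
  the mean rate of its valid 8-neighbors (local smoothness), with Fisher Z.
* Spatial information: occupancy-weighted information rate
  I = sum_x p(x) * lam(x) * log2(lam(x)/lam_bar)  [bits/s],
  where p(x) is the occupancy probability of pixel x (renormalized over valid
  pixels) and lam_bar = sum_x p(x) lam(x) is the occupancy-weighted mean rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .exceptions import EmptyFieldError, UndefinedCoherenceError
from .maps import PlaceField, RateMap

_CLIP = 1.0 - 1e-7  # correlation clip before atanh


def fisher_z(r: float) -> float:
    """Fisher Z transform atanh(r), with r clipped to +/-(1 - 1e-7)."""
    return float(np.arctanh(np.clip(r, -_CLIP, _CLIP)))


@dataclass
class SpatialMetrics:
    """All scalar spatial statistics reported per cell-session."""

    overall_rate: float  # occupancy-weighted mean rate lam_bar, Hz
    in_field_rate: float
    out_field_rate: float
    selectivity: float  # log10 units; +inf sentinel if out-field rate is 0
    coherence_r: float
    coherence_z: float
    information_rate: float  # bits/s
    field_size: int  # pixels, above-mean definition


def in_out_field_rates(ratemap: RateMap, pfield: PlaceField) -> tuple[float, float]:
    """Mean rate over field pixels and over valid non-field pixels."""
    infield = pfield.member & ratemap.valid
    outfield = ratemap.valid & ~pfield.member
    if not infield.any():
        raise EmptyFieldError("place field is empty")
    if not outfield.any():
        raise EmptyFieldError("place-field complement is empty")
    return float(ratemap.rate[infield].mean()), float(ratemap.rate[outfield].mean())


def spatial_selectivity(ratemap: RateMap, pfield: PlaceField) -> float:
    """log10(in-field mean rate / out-field mean rate).

    Returns ``inf`` when the out-field mean is 0 (flagged sentinel; callers
    exclude it from averages) and ``-inf`` when the in-field mean is 0.
    """
    rin, rout = in_out_field_rates(ratemap, pfield)
    if rout == 0.0:
        return math.inf
    if rin == 0.0:
        return -math.inf
    return math.log10(rin / rout)


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


def spatial_coherence(ratemap: RateMap) -> tuple[float, float]:
    """(r, Fisher Z) of each pixel's rate against its valid-8-neighbor mean.

    Pixels with no valid neighbor are skipped.  Raises
    :class:`UndefinedCoherenceError` when either side has zero variance
    (e.g. a constant map).
    """
    v = ratemap.valid.astype(float)
    nb_sum = ndimage.convolve(ratemap.rate * v, _NEIGHBOR_KERNEL, mode="constant")
    nb_cnt = ndimage.convolve(v, _NEIGHBOR_KERNEL, mode="constant")
    sel = ratemap.valid & (nb_cnt > 0.5)
    if sel.sum() < 3:
        raise UndefinedCoherenceError("fewer than 3 pixels with valid neighbors")
    center = ratemap.rate[sel]
    neighbor = nb_sum[sel] / nb_cnt[sel]
    if np.ptp(center) == 0.0 or np.ptp(neighbor) == 0.0:
        raise UndefinedCoherenceError("zero variance in pixel rates or neighbor means")
    r = float(stats.pearsonr(center, neighbor).statistic)
    return r, fisher_z(r)


def spatial_information(ratemap: RateMap) -> float:
    """Information rate I = sum p(x) lam(x) log2(lam(x)/lam_bar), bits/s.

    p(x) renormalizes occupancy over valid pixels; terms with lam(x) = 0
    contribute 0.  Raises ``ValueError`` when lam_bar = 0.
    """
    occ = ratemap.occupancy[ratemap.valid]
    lam = ratemap.rate[ratemap.valid]
    total = occ.sum()
    if total <= 0:
        raise EmptyFieldError("no occupancy on valid pixels")
    p = occ / total
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        raise ValueError("overall mean rate is 0; information undefined")
    pos = lam > 0
    return float(np.sum(p[pos] * lam[pos] * np.log2(lam[pos] / lam_bar)))


def occupancy_weighted_rate(ratemap: RateMap) -> float:
    """lam_bar: occupancy-weighted mean firing rate over valid pixels, Hz."""
    occ = ratemap.occupancy[ratemap.valid]
    lam = ratemap.rate[ratemap.valid]
    total = occ.sum()
    if total <= 0:
        raise EmptyFieldError("no occupancy on valid pixels")
    return float(np.sum(occ * lam) / total)


def compute_spatial_metrics(ratemap: RateMap, pfield: PlaceField | None = None) -> SpatialMetrics:
    """All spatial statistics of one map (field defaults to above-mean)."""
    if pfield is None:
        from .maps import define_place_field

        pfield = define_place_field(ratemap, "above_mean")
    rin, rout = in_out_field_rates(ratemap, pfield)
    sel = spatial_selectivity(ratemap, pfield)
    try:
        r, z = spatial_coherence(ratemap)
    except UndefinedCoherenceError:
        r, z = math.nan, math.nan
    return SpatialMetrics(
        overall_rate=occupancy_weighted_rate(ratemap),
        in_field_rate=rin,
        out_field_rate=rout,
        selectivity=sel,
        coherence_r=r,
        coherence_z=z,
        information_rate=spatial_information(ratemap),
        field_size=pfield.size if pfield.definition_mode == "above_mean" else -1,
    )
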