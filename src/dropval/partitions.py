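"""Droplet classification: cluster statistics, thresholds, rain and well QC.

A single-channel ddPCR well shows two fluorescence clusters — negative
droplets around a low amplitude and positive droplets around a high one —
plus possibly "rain": droplets of ambiguous, intermediate amplitude.
Cluster boundaries are taken as mean ± 4·SD; rain is anything strictly
between the negative cluster's upper boundary and the positive cluster's
lower boundary.  Three threshold variants bracket the impact of rain on
the result: the midpoint threshold (routine choice), a low threshold at
the negative boundary (all rain positive), and a high threshold at the
positive boundary (all rain negative); a fourth re-analysis drops rain
droplets from the accepted count altogether.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .records import DropletWell, QCReport, WellResult

__all__ = [
    "ClusterStats",
    "ThresholdSet",
    "estimate_clusters",
    "make_thresholds",
    "classify",
    "qc_well",
    "selectivity_metrics",
]

#: Cluster half-width in SD units; mean ± 4 SD contains essentially the
#: whole cluster under normality.
CLUSTER_SD_MULTIPLE = 4.0


@dataclass
class ClusterStats:
    """Per-well (or per-plate) fluorescence cluster summary."""

    neg_mean: float
    neg_sd: float
    pos_mean: float
    pos_sd: float
    n_neg: int
    n_pos: int

    @property
    def single_cluster(self) -> bool:
        return self.n_neg == 0 or self.n_pos == 0

    def __post_init__(self) -> None:
        if (self.neg_sd is not None and not math.isnan(self.neg_sd) and self.neg_sd < 0) or (
            self.pos_sd is not None and not math.isnan(self.pos_sd) and self.pos_sd < 0
        ):
            raise ValueError("cluster SDs must be >= 0")
        if not self.single_cluster and not self.pos_mean > self.neg_mean:
            raise ValueError("positive cluster mean must exceed negative cluster mean")


@dataclass
class ThresholdSet:
    """The three classification thresholds derived from cluster stats.

    ``midpoint`` sits halfway between the cluster means; ``low`` at the
    negative cluster's upper boundary (mean + 4·SD); ``high`` at the
    positive cluster's lower boundary (mean − 4·SD).  ``low <= high`` is
    required for rain analysis but not enforced here (heavily overlapping
    clusters legitimately produce low > high, which rain-aware operations
    reject).
    """

    midpoint: float
    low: float
    high: float


def estimate_clusters(
    amplitudes: Sequence[float], init_threshold: Optional[float] = None
) -> ClusterStats:
    """Split droplet amplitudes into two clusters and summarise them.

    Starts from ``init_threshold`` (default: midpoint of the amplitude
    range) and iterates splitting at the midpoint of the two cluster means
    until assignments are stable — i.e. 1-D two-means.  This automates the
    analyst's by-eye cluster identification; a manually chosen plate
    threshold can be passed downstream instead.

    Returns a flagged one-cluster result (all droplets in the negative
    slot, positive stats nan) when the split leaves one side empty, e.g.
    for a blank well or identical amplitudes.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size == 0:
        raise ValueError("empty amplitude vector")
    if a.size < 2:
        raise ValueError("need at least 2 droplets to estimate clusters")

    def _one_cluster() -> ClusterStats:
        sd = float(a.std(ddof=1)) if a.size > 1 else 0.0
        return ClusterStats(float(a.mean()), sd, math.nan, math.nan, int(a.size), 0)

    if np.ptp(a) == 0:
        return _one_cluster()
    thr = float(init_threshold) if init_threshold is not None else (a.min() + a.max()) / 2.0
    for _ in range(200):
        hi = a >= thr
        if hi.all() or not hi.any():
            return _one_cluster()
        lo_mean = float(a[~hi].mean())
        hi_mean = float(a[hi].mean())
        new_thr = (lo_mean + hi_mean) / 2.0
        if new_thr == thr:
            break
        thr = new_thr
    hi = a >= thr
    neg, pos = a[~hi], a[hi]
    return ClusterStats(
        neg_mean=float(neg.mean()),
        neg_sd=float(neg.std(ddof=1)) if neg.size > 1 else 0.0,
        pos_mean=float(pos.mean()),
        pos_sd=float(pos.std(ddof=1)) if pos.size > 1 else 0.0,
        n_neg=int(neg.size),
        n_pos=int(pos.size),
    )


def make_thresholds(clusters: ClusterStats) -> ThresholdSet:
    """Midpoint / low / high thresholds from two-cluster statistics."""
    if clusters.single_cluster:
        raise ValueError("cannot derive thresholds from a one-cluster well")
    return ThresholdSet(
        midpoint=(clusters.neg_mean + clusters.pos_mean) / 2.0,
        low=clusters.neg_mean + CLUSTER_SD_MULTIPLE * clusters.neg_sd,
        high=clusters.pos_mean - CLUSTER_SD_MULTIPLE * clusters.pos_sd,
    )


def classify(
    well: DropletWell,
    threshold: float,
    rain_removal: bool = False,
    bounds: Optional[ThresholdSet] = None,
    threshold_variant: Optional[str] = None,
) -> WellResult:
    """Count positive droplets at ``threshold``; optionally drop rain.

    A droplet is positive iff its amplitude is >= the threshold (ties count
    positive).  Rain droplets are those strictly between ``bounds.low`` and
    ``bounds.high``; with ``rain_removal=True`` they are removed from both
    the positive and the accepted count before quantification.
    """
    if well.amplitudes is None:
        raise ValueError(f"well {well.well_id} has no amplitude data to classify")
    a = well.amplitudes
    rain_mask = None
    n_rain = 0
    if bounds is not None:
        if bounds.low > bounds.high:
            if rain_removal:
                raise ValueError(
                    "rain analysis requires low <= high cluster boundaries"
                )
        else:
            rain_mask = (a > bounds.low) & (a < bounds.high)
            n_rain = int(rain_mask.sum())
    if rain_removal:
        if bounds is None:
            raise ValueError("rain_removal requires cluster bounds")
        keep = ~rain_mask
        P = int((a[keep] >= threshold).sum())
        A = int(keep.sum())
    else:
        P = int((a >= threshold).sum())
        A = well.accepted
    return WellResult(
        well_id=well.well_id,
        P=P,
        A=A,
        rain=n_rain,
        threshold=float(threshold),
        run_id=well.run_id,
        level_id=well.level_id,
        assay_id=well.assay_id,
        threshold_variant=threshold_variant
        or ("rain_removal" if rain_removal else well.threshold_variant),
        df_sample=well.df_sample,
        df_pcr=well.df_pcr,
    )


def _robust_z(value: float, values: np.ndarray) -> float:
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    dev = abs(value - med)
    if mad == 0.0:
        return math.inf if dev > 0 else 0.0
    return dev / (1.4826 * mad)


def qc_well(
    well: DropletWell,
    plate_stats: Optional[Sequence[ClusterStats]] = None,
    *,
    reference: Optional[ClusterStats] = None,
    min_droplets: int = 10_000,
    tail_fraction: float = 0.05,
    outlier_mad_multiple: float = 5.0,
) -> QCReport:
    """Apply the three technical well-exclusion rules.

    (i)  ``min_droplets`` — fewer than 10,000 accepted droplets;
    (ii) ``amplitude_outlier`` — the well's cluster means are clearly
         different from the other wells on the plate, operationalised as a
         robust z-score (vs the plate median, scaled by the plate MAD)
         above ``outlier_mad_multiple`` for either cluster mean;
    (iii) ``low_amplitude_tail`` — at least ``tail_fraction`` of accepted
         droplets lie significantly below the negative cluster, i.e. under
         its lower boundary (mean − 4·SD).

    Rules (ii)–(iii) need amplitudes; without them they are reported
    "not evaluated" and do not fail the well.  ``reference`` supplies the
    negative-cluster statistics for rule (iii) (e.g. the plate-level
    clusters); by default the well's own estimate is used and, for rule
    (ii), the per-well estimates of the whole plate.
    """
    failed: list[str] = []
    details: dict = {"accepted": well.accepted}
    if well.accepted < min_droplets:
        failed.append("min_droplets")

    if well.amplitudes is None:
        details["amplitude_outlier"] = "not evaluated"
        details["low_amplitude_tail"] = "not evaluated"
    else:
        own = estimate_clusters(well.amplitudes)
        ref = reference if reference is not None else own
        lower_bound = ref.neg_mean - CLUSTER_SD_MULTIPLE * ref.neg_sd
        frac = float((well.amplitudes < lower_bound).mean())
        details["low_amplitude_tail"] = frac
        if frac >= tail_fraction:
            failed.append("low_amplitude_tail")

        if plate_stats is not None and len(plate_stats) >= 3:
            usable = [s for s in plate_stats if not s.single_cluster]
            if len(usable) >= 3 and not own.single_cluster:
                z_neg = _robust_z(
                    own.neg_mean, np.array([s.neg_mean for s in usable])
                )
                z_pos = _robust_z(
                    own.pos_mean, np.array([s.pos_mean for s in usable])
                )
                details["amplitude_outlier"] = {"z_neg": z_neg, "z_pos": z_pos}
                if max(z_neg, z_pos) > outlier_mad_multiple:
                    failed.append("amplitude_outlier")
            else:
                details["amplitude_outlier"] = "not evaluated"
        else:
            details["amplitude_outlier"] = "not evaluated"

    return QCReport(passed=not failed, failed_rules=tuple(failed), details=details)


def _counts(well, threshold: Optional[float]) -> tuple[int, int]:
    if isinstance(well, WellResult):
        return well.P, well.A
    if well.positives is not None:
        return well.positives, well.accepted
    if well.amplitudes is not None and threshold is not None:
        return int((well.amplitudes >= threshold).sum()), well.accepted
    raise ValueError(
        f"well {well.well_id}: no positive count and no amplitudes/threshold"
    )


def selectivity_metrics(
    blank_wells: Sequence,
    positive_wells: Sequence,
    threshold: Optional[float] = None,
) -> tuple[float, float]:
    """Pooled false-positive and false-negative droplet fractions.

    The false-positive fraction is the pooled fraction of positive
    droplets across matrix-blank wells; the false-negative fraction is the
    pooled fraction of negative droplets across high-concentration
    positive-control wells.  Wells may be :class:`WellResult`, or
    :class:`DropletWell` with counts or with amplitudes (then classified
    at ``threshold``).
    """
    fp_num = fp_den = fn_num = fn_den = 0
    for w in blank_wells:
        p, a = _counts(w, threshold)
        fp_num += p
        fp_den += a
    for w in positive_wells:
        p, a = _counts(w, threshold)
        fn_num += a - p
        fn_den += a
    if fp_den == 0 or fn_den == 0:
        raise ValueError("zero accepted droplets in one of the groups")
    return fp_num / fp_den, fn_num / fn_den
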