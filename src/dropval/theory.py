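"""Closed-form stochastic-effect predictions for digital PCR.

Two stochastic stages limit the precision of a dPCR result at the ends of
the working range:

* **sampling** — the number of target copies pipetted into the PCR mix is
  Poisson, so the relative SD of the sampled copy number T is 1/sqrt(T);
* **distribution** — the copies are scattered over A droplets and only
  the positive/negative pattern is observed.  With mean occupancy
  λ = c·Vd, the positive count is Binomial(A, 1 − e^(−λ)) and the delta
  method gives the relative SD of the estimator λ̂ = −ln(1 − P/A) as

      s_distribution,rel = sqrt((e^λ − 1)/A) / λ,

  which tends to 1/sqrt(Aλ) (pure Poisson counting) as λ → 0 and blows up
  as the droplets saturate.

Because Poisson sampling thins exactly, the replicate-to-replicate SD of
the concentration estimate for the analysed droplets equals the
distribution component alone; :func:`stochastic_rel_std` returns it.  The
quadrature combination of both components (the conventional cause-tree
view, treating the mix-sampling stage as an extra independent source) is
carried on each :class:`StochasticPoint` as ``s_stochastic_rel``.

Also provided: the theoretical minimum detection limit — the
concentration whose analysed volume has probability ``alpha`` of
containing zero copies — and a simulation of the maximum
threshold-setting uncertainty as a function of the rain proportion.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .partitions import ClusterStats, classify, make_thresholds
from .quantify import concentration_from_counts
from .simulate import SimulationConfig, simulate_well
from .validation import threshold_variability

__all__ = [
    "StochasticPoint",
    "sampling_rel_std",
    "distribution_rel_std",
    "stochastic_rel_std",
    "stochastic_curve",
    "theoretical_min_lod",
    "max_threshold_uncertainty_sim",
]


@dataclass(frozen=True)
class StochasticPoint:
    """Stochastic-effect summary at one PCR concentration."""

    c_pcr: float
    t_sampled: float
    t_analysed: float
    a: int
    s_sampling_rel: float
    s_distribution_rel: float
    s_stochastic_rel: float


def sampling_rel_std(t_sampled: float) -> float:
    """Poisson relative SD of the number of copies sampled into the mix."""
    if t_sampled <= 0:
        raise ValueError("expected sampled copy number must be > 0")
    return 1.0 / math.sqrt(t_sampled)


def distribution_rel_std(lambda_per_droplet: float, a: int) -> float:
    """Delta-method relative SD of the occupancy estimator λ̂ = −ln(1−P/A)."""
    if lambda_per_droplet <= 0:
        raise ValueError("mean occupancy must be > 0")
    if a < 2:
        raise ValueError("need at least 2 droplets")
    return math.sqrt(math.expm1(lambda_per_droplet) / a) / lambda_per_droplet


def stochastic_rel_std(
    c_pcr: float, a: int = 17_000, droplet_volume_nl: float = 0.834
) -> float:
    """Relative SD of a single-well concentration estimate.

    Equals the distribution component at occupancy λ = c·Vd: under exact
    Poisson thinning the analysed droplets are i.i.d. Poisson(λ) occupied
    regardless of how the mix was sampled, so no separate sampling term
    enters the per-well replicate SD.
    """
    lam = c_pcr * droplet_volume_nl * 1e-3
    return distribution_rel_std(lam, a)


def stochastic_curve(
    c_grid: Sequence[float],
    a: int = 17_000,
    droplet_volume_nl: float = 0.834,
    sampled_volume_ul: float = 20.0,
) -> list[StochasticPoint]:
    """Sampling / distribution / combined relative SDs over a concentration grid."""
    if a < 2 or droplet_volume_nl <= 0 or sampled_volume_ul <= 0:
        raise ValueError("inputs must be positive (and A >= 2)")
    vd_ul = droplet_volume_nl * 1e-3
    points = []
    for c in c_grid:
        if c <= 0:
            raise ValueError("concentrations must be > 0")
        t_sampled = c * sampled_volume_ul
        lam = c * vd_ul
        s_samp = sampling_rel_std(t_sampled)
        s_dist = distribution_rel_std(lam, a)
        points.append(
            StochasticPoint(
                c_pcr=float(c),
                t_sampled=t_sampled,
                t_analysed=lam * a,
                a=a,
                s_sampling_rel=s_samp,
                s_distribution_rel=s_dist,
                s_stochastic_rel=math.hypot(s_samp, s_dist),
            )
        )
    return points


def theoretical_min_lod(
    a: int, droplet_volume_nl: float = 0.834, alpha: float = 0.05
) -> float:
    """Smallest detectable concentration for ``a`` analysed droplets.

    The concentration at which the analysed volume ``a·Vd`` contains zero
    copies with probability ``alpha``:  c = −ln(alpha)/(a·Vd), in
    copies/µL.  Below it, more than ``alpha`` of measurements are blind to
    the target no matter how the droplets are classified.
    """
    if a < 1:
        raise ValueError("need at least 1 analysed droplet")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be > 0")
    return -math.log(alpha) / (a * droplet_volume_nl * 1e-3)


def max_threshold_uncertainty_sim(
    rain_fraction_grid: Sequence[float],
    c_pcr: float,
    config: SimulationConfig,
    n_reps: int,
    rng: Union[np.random.Generator, int, None] = None,
) -> list[tuple[float, float]]:
    """Maximum threshold-setting uncertainty vs rain proportion, by simulation.

    For each rain fraction, simulates ``n_reps`` wells, re-analyses each
    under the four variants (midpoint, low, high, rain removal — bounds
    from the generating cluster parameters) and applies the
    threshold-variability ANOVA.  Returns ``(rain_fraction, s_thres_rel)``
    pairs.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates per rain fraction")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    clusters = ClusterStats(
        neg_mean=config.neg_cluster[0],
        neg_sd=config.neg_cluster[1],
        pos_mean=config.pos_cluster[0],
        pos_sd=config.pos_cluster[1],
        n_neg=1,
        n_pos=1,
    )
    thresholds = make_thresholds(clusters)
    out = []
    for f in rain_fraction_grid:
        cfg = dataclasses.replace(
            config, true_concentration=c_pcr, rain_fraction=float(f),
            emit_amplitudes=True,
        )
        per_replicate = []
        for i in range(n_reps):
            well = simulate_well(cfg, rng, well_id=f"r{i}")
            variants = []
            for thr, removal in (
                (thresholds.midpoint, False),
                (thresholds.low, False),
                (thresholds.high, False),
                (thresholds.midpoint, True),
            ):
                res = classify(well, thr, rain_removal=removal, bounds=thresholds)
                if res.P == res.A or res.A < 2:
                    continue
                variants.append(
                    concentration_from_counts(
                        res.P, res.A, droplet_volume_nl=config.droplet_volume_nl
                    )[0]
                )
            per_replicate.append(variants)
        out.append((float(f), threshold_variability(per_replicate)))
    return out
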