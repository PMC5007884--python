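"""Synthetic droplet-plate generator.

Generates wells with the statistical structure the analysis assumes:

* accepted droplet count per well — rounded truncated normal (>= 1);
* total target copies in the analysed droplets — Poisson with mean
  ``c_pcr * A * Vd`` (copies/µL times analysed volume in µL).  Placing the
  copies directly in the analysed volume is statistically identical to
  two-stage sampling (into the 20 µL PCR mix, then into the droplets)
  because Poisson thinning preserves the Poisson law; the two-stage
  variant is available via ``two_stage_sampling`` for didactic comparison;
* copies scattered uniformly over the droplets (multinomial occupancy,
  realised as K uniform index draws); droplets holding >= 1 copy draw
  their amplitude from the positive cluster, the rest from the negative
  cluster.  Cluster amplitudes are truncated normals at ±4 SD so the
  mean ± 4·SD boundaries contain the clusters exactly;
* optional "rain": a Binomial(A, rain_fraction) subset re-assigned a
  uniform amplitude strictly between the cluster boundaries;
* optional multiplicative per-run and per-assay concentration effects and
  a per-run droplet-volume perturbation.

Ground truth (true concentration, pre-rain positive count, injected rain
count) is recorded in each well's ``meta``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .quantify import GravimetricRecord, gravimetric_dilution_factor
from .records import DropletWell

__all__ = [
    "SimulationConfig",
    "StudyDesign",
    "simulate_well",
    "simulate_validation_study",
    "simulate_dilution_series",
]

_TRUNC = 4.0  # cluster half-width in SDs; matches the boundary definition


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults reproduce the validated method's plates.

    ``true_concentration`` is the copy-number concentration in the PCR mix
    (copies/µL).  Droplet counts default to the instrument-typical ~17,000
    accepted droplets of 0.834 nL; cluster amplitudes default to the
    observed negative (1764 ± 135) and positive (5418 ± 212) clusters.
    ``droplet_volume_rel_sd`` (1.8 %) records the relative standard
    uncertainty of the assigned droplet volume; it perturbs simulated
    volumes only where explicitly requested (see
    :func:`simulate_validation_study`).
    """

    true_concentration: float
    droplet_count_mean: float = 17_000.0
    droplet_count_sd: float = 1_000.0
    droplet_volume_nl: float = 0.834
    droplet_volume_rel_sd: float = 0.018
    neg_cluster: tuple[float, float] = (1764.0, 135.0)
    pos_cluster: tuple[float, float] = (5418.0, 212.0)
    rain_fraction: float = 0.0
    run_effect_rel_sd: float = 0.0
    assay_effect_rel_sd: float = 0.0
    emit_amplitudes: bool = True
    two_stage_sampling: bool = False
    pcr_mix_volume_ul: float = 20.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.true_concentration < 0:
            raise ValueError("true_concentration must be >= 0")
        if self.droplet_count_mean <= 0:
            raise ValueError("droplet_count_mean must be > 0")
        for name in (
            "droplet_count_sd",
            "droplet_volume_rel_sd",
            "run_effect_rel_sd",
            "assay_effect_rel_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.rain_fraction <= 1.0:
            raise ValueError("rain_fraction must be in [0, 1]")
        if self.droplet_volume_nl <= 0:
            raise ValueError("droplet_volume_nl must be > 0")
        if not self.pos_cluster[0] > self.neg_cluster[0]:
            raise ValueError("positive cluster mean must exceed negative cluster mean")
        if self.rain_fraction > 0 and self.rain_low_bound >= self.rain_high_bound:
            raise ValueError(
                "cluster boundaries overlap (neg mean + 4 SD >= pos mean - 4 SD); "
                "no rain band exists"
            )

    @property
    def rain_low_bound(self) -> float:
        return self.neg_cluster[0] + _TRUNC * self.neg_cluster[1]

    @property
    def rain_high_bound(self) -> float:
        return self.pos_cluster[0] - _TRUNC * self.pos_cluster[1]


@dataclass
class StudyDesign:
    """A set of simulated (or loaded) wells plus the design ground truth."""

    wells: list[DropletWell]
    truth: dict = field(default_factory=dict)

    def by_run(self, level_id: Optional[str] = None) -> dict[str, list[DropletWell]]:
        groups: dict[str, list[DropletWell]] = {}
        for w in self.wells:
            if level_id is not None and w.level_id != level_id:
                continue
            groups.setdefault(w.run_id, []).append(w)
        return groups

    def levels(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.level_id)
        return list(seen)


def _as_rng(rng: Union[np.random.Generator, int, None]) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _truncnorm(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) truncated at ±4 SD, by rejection (p_reject ≈ 6e-5)."""
    if sd == 0 or size == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = np.abs(out - mean) > _TRUNC * sd
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = np.abs(out - mean) > _TRUNC * sd
    return out


def simulate_well(
    config: SimulationConfig,
    rng: Union[np.random.Generator, int, None] = None,
    *,
    well_id: str = "A01",
    run_id: str = "run1",
    level_id: str = "",
    assay_id: str = "",
    run_factor: float = 1.0,
    volume_factor: float = 1.0,
    assay_factor: float = 1.0,
    df_sample: float = 1.0,
    df_pcr: float = 1.0,
) -> DropletWell:
    """Draw one well from the generative model.

    ``run_factor`` / ``assay_factor`` / ``volume_factor`` are multiplicative
    effects drawn at the run/assay level by the study-level simulators and
    applied here; at the defaults the well is an i.i.d. replicate.
    """
    rng = _as_rng(rng if rng is not None else config.seed)

    # accepted droplets: rounded normal truncated below at 1 (rejection;
    # at the default mean/sd the truncation essentially never triggers)
    if config.droplet_count_sd > 0:
        a_draw = float(rng.normal(config.droplet_count_mean, config.droplet_count_sd))
        for _ in range(100):
            if a_draw >= 1.0:
                break
            a_draw = float(
                rng.normal(config.droplet_count_mean, config.droplet_count_sd)
            )
        a_draw = max(a_draw, 1.0)
    else:
        a_draw = config.droplet_count_mean
    A = max(1, int(round(a_draw)))

    vd_ul = config.droplet_volume_nl * 1e-3 * volume_factor
    c_eff = config.true_concentration * run_factor * assay_factor

    if config.two_stage_sampling:
        analysed_ul = A * vd_ul
        if analysed_ul > config.pcr_mix_volume_ul:
            raise ValueError("analysed volume exceeds the PCR mix volume")
        k_mix = rng.poisson(c_eff * config.pcr_mix_volume_ul)
        K = rng.binomial(k_mix, analysed_ul / config.pcr_mix_volume_ul)
    else:
        K = rng.poisson(c_eff * A * vd_ul)

    # multinomial occupancy == K uniform droplet-index draws
    occupied = np.unique(rng.integers(0, A, size=int(K)))
    true_positives = int(occupied.size)

    meta = {
        "true_concentration": config.true_concentration,
        "effective_concentration": c_eff,
        "true_positives": true_positives,
        "copies_in_analysed": int(K),
        "rain_injected": 0,
    }

    amplitudes = None
    positives: Optional[int] = true_positives
    if config.emit_amplitudes:
        neg_m, neg_s = config.neg_cluster
        pos_m, pos_s = config.pos_cluster
        amps = _truncnorm(rng, neg_m, neg_s, A)
        amps[occupied] = _truncnorm(rng, pos_m, pos_s, true_positives)
        if config.rain_fraction > 0:
            n_rain = rng.binomial(A, config.rain_fraction)
            if n_rain > 0:
                idx = rng.choice(A, size=n_rain, replace=False)
                amps[idx] = rng.uniform(
                    config.rain_low_bound, config.rain_high_bound, size=n_rain
                )
                meta["rain_injected"] = int(n_rain)
        amplitudes = amps
        positives = None  # classification derives P from a threshold

    return DropletWell(
        well_id=well_id,
        accepted=A,
        amplitudes=amplitudes,
        positives=positives,
        run_id=run_id,
        level_id=level_id,
        assay_id=assay_id,
        df_sample=df_sample,
        df_pcr=df_pcr,
        meta=meta,
    )


def simulate_validation_study(
    levels: Sequence[float],
    n_runs: int,
    n_replicates_per_run: Union[int, Sequence[int]],
    run_effect_rel_sd: float,
    config: SimulationConfig,
    rng: Union[np.random.Generator, int, None] = None,
    *,
    level_ids: Optional[Sequence[str]] = None,
    assay_id: str = "",
    perturb_volume: bool = False,
) -> StudyDesign:
    """Simulate a nested precision study: runs × replicates at each level.

    Per run one multiplicative concentration factor ~ Normal(1,
    ``run_effect_rel_sd``) is drawn and applied to every well of that run;
    replicate counts may differ per run (unbalanced designs).  With
    ``perturb_volume=True`` each run additionally draws a droplet-volume
    factor ~ Normal(1, ``config.droplet_volume_rel_sd``).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = _as_rng(rng)
    if isinstance(n_replicates_per_run, int):
        reps = [n_replicates_per_run] * n_runs
    else:
        reps = list(n_replicates_per_run)
        if len(reps) != n_runs:
            raise ValueError("one replicate count per run required")
    if level_ids is None:
        level_ids = [f"L{i + 1}" for i in range(len(levels))]

    run_factors = [
        float(rng.normal(1.0, run_effect_rel_sd)) if run_effect_rel_sd > 0 else 1.0
        for _ in range(n_runs)
    ]
    vol_factors = [
        float(rng.normal(1.0, config.droplet_volume_rel_sd))
        if perturb_volume and config.droplet_volume_rel_sd > 0
        else 1.0
        for _ in range(n_runs)
    ]

    wells: list[DropletWell] = []
    for r in range(n_runs):
        run_id = f"run{r + 1}"
        for lid, conc in zip(level_ids, levels):
            lvl_cfg = dataclasses.replace(config, true_concentration=conc)
            for i in range(reps[r]):
                wells.append(
                    simulate_well(
                        lvl_cfg,
                        rng,
                        well_id=f"{run_id}-{lid}-{i + 1:02d}",
                        run_id=run_id,
                        level_id=lid,
                        assay_id=assay_id,
                        run_factor=run_factors[r],
                        volume_factor=vol_factors[r],
                    )
                )
    truth = {
        "levels": dict(zip(level_ids, map(float, levels))),
        "run_factors": run_factors,
        "volume_factors": vol_factors,
        "run_effect_rel_sd": run_effect_rel_sd,
    }
    return StudyDesign(wells=wells, truth=truth)


def simulate_dilution_series(
    stock_concentration: float,
    gravimetric_records: Sequence[GravimetricRecord],
    config: SimulationConfig,
    rng: Union[np.random.Generator, int, None] = None,
    *,
    n_replicates: int = 1,
) -> StudyDesign:
    """Simulate wells along a gravimetric dilution series.

    Each record describes one weighing step; dilution factors accumulate
    multiplicatively and wells are simulated at each step's expected
    concentration (level ids ``dil1``, ``dil2``, ...).
    """
    if stock_concentration < 0:
        raise ValueError("stock concentration must be >= 0")
    rng = _as_rng(rng)
    wells: list[DropletWell] = []
    expected: dict[str, float] = {}
    df_total = 1.0
    for step, rec in enumerate(gravimetric_records, start=1):
        df_total *= gravimetric_dilution_factor(rec)
        conc = stock_concentration / df_total
        lid = f"dil{step}"
        expected[lid] = conc
        step_cfg = dataclasses.replace(config, true_concentration=conc)
        for i in range(n_replicates):
            wells.append(
                simulate_well(
                    step_cfg,
                    rng,
                    well_id=f"{lid}-{i + 1:02d}",
                    level_id=lid,
                    df_sample=df_total,
                )
            )
    return StudyDesign(
        wells=wells,
        truth={"levels": expected, "stock_concentration": float(stock_concentration)},
    )
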