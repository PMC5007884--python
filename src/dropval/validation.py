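"""Single-laboratory validation statistics for a dPCR method.

Nested-precision analysis in the ISO 5725-3 / GUM style: replicate
concentrations grouped per run feed a one-way ANOVA whose mean squares
yield the relative repeatability

    s_repeat,rel = sqrt(MS_within) / c_mean

and the relative run-to-run variation

    s_run,rel = sqrt((MS_between - MS_within) / n_repli_bar) / c_mean,

clamped to zero (and flagged) when MS_between < MS_within.  The standard
uncertainty of a mean over ``n_run`` runs of ``n_repli_bar`` replicates is

    u_precision,rel = sqrt(s_repeat²/(n_repli_bar·n_run) + s_run²/n_run).

Per-level estimates are pooled by root mean square.  Trueness is assessed
against certified reference levels: relative bias per level, its mean, and

    u_bias,rel = sqrt(u_precision,pooled² + Σ u_cert,i² / n_cert),

with expanded U_bias = 2·u_bias; the mean bias is significant only if its
magnitude exceeds U_bias.  Remaining components (droplet volume, assay,
threshold setting) join the combined expanded uncertainty (k = 2)

    U_meas,rel = 2·sqrt(s_repeat²/n_meas + s_run²/n_run + u_Vd² + u_bias²
                        [+ s_thres²]).

All relative quantities are carried as fractions; multiply by 100 only at
the reporting boundary.
"""
from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "CertifiedLevel",
    "PrecisionEstimate",
    "BiasEstimate",
    "UncertaintyBudget",
    "one_way_anova",
    "precision_from_runs",
    "pool_rms",
    "bias_assessment",
    "assay_variability",
    "threshold_variability",
    "combined_uncertainty",
    "linearity_fit",
    "lod_experimental",
    "loq_assess",
    "robustness_compare",
]


@dataclass(frozen=True)
class CertifiedLevel:
    """One certified reference level: value and expanded uncertainty.

    ``u_cert`` is the *expanded* uncertainty from the certificate; CRM
    certificates state it with coverage factor k = 2, so the relative
    standard uncertainty is ``(u_cert / 2) / c_cert``.
    """

    level_id: str
    c_cert: float
    u_cert: float
    coverage_k: float = 2.0

    def __post_init__(self) -> None:
        if self.c_cert <= 0:
            raise ValueError("certified concentration must be > 0")
        if self.u_cert < 0:
            raise ValueError("expanded uncertainty must be >= 0")

    @property
    def u_cert_rel(self) -> float:
        return (self.u_cert / self.coverage_k) / self.c_cert


AnovaDecomposition = namedtuple(
    "AnovaDecomposition", "ms_within ms_between n_bar grand_mean n_groups n_total"
)


@dataclass
class PrecisionEstimate:
    s_repeat_rel: float
    s_run_rel: float
    u_precision_rel: float
    ms_within: float
    ms_between: float
    n_runs: int
    n_bar_repli: float
    mean_concentration: float
    run_sd_clamped: bool = False


@dataclass
class BiasEstimate:
    bias_rel: dict[str, float]
    mean_bias_rel: float
    u_bias_rel: float
    U_bias_rel: float
    significant: bool


@dataclass
class UncertaintyBudget:
    """Named relative components and the combined expanded uncertainty."""

    s_repeat_pooled_rel: float
    s_run_pooled_rel: float
    u_precision_pooled_rel: float
    u_vd_rel: float
    u_bias_rel: float
    s_assay_rel: Optional[float] = None
    s_thres_rel: Optional[float] = None
    n_meas: int = 4
    n_runs: int = 1
    U_meas_rel: float = math.nan
    notes: dict = field(default_factory=dict)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaDecomposition:
    """Standard one-way variance decomposition over (possibly unbalanced) groups.

    MS_within = Σ_g Σ_i (x_gi − x̄_g)² / (N − k);
    MS_between = Σ_g n_g (x̄_g − x̄)² / (k − 1);
    n_bar is the arithmetic mean group size.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    n_total = sum(a.size for a in arrs)
    if n_total == k:
        raise ValueError("all groups are singletons: MS_within undefined")
    grand = float(np.concatenate(arrs).mean())
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrs)
    ss_between = sum(a.size * (float(a.mean()) - grand) ** 2 for a in arrs)
    return AnovaDecomposition(
        ms_within=ss_within / (n_total - k),
        ms_between=ss_between / (k - 1),
        n_bar=n_total / k,
        grand_mean=grand,
        n_groups=k,
        n_total=n_total,
    )


def precision_from_runs(runs: Sequence[Sequence[float]]) -> PrecisionEstimate:
    """Repeatability / run-to-run SDs and precision uncertainty from run groups."""
    a = one_way_anova(runs)
    c = a.grand_mean
    if c == 0:
        raise ValueError("zero mean concentration: relative SDs undefined")
    s_repeat = math.sqrt(a.ms_within) / abs(c)
    clamped = a.ms_between < a.ms_within
    s_run = (
        0.0
        if clamped
        else math.sqrt((a.ms_between - a.ms_within) / a.n_bar) / abs(c)
    )
    u_prec = math.sqrt(
        s_repeat**2 / (a.n_bar * a.n_groups) + s_run**2 / a.n_groups
    )
    return PrecisionEstimate(
        s_repeat_rel=s_repeat,
        s_run_rel=s_run,
        u_precision_rel=u_prec,
        ms_within=a.ms_within,
        ms_between=a.ms_between,
        n_runs=a.n_groups,
        n_bar_repli=a.n_bar,
        mean_concentration=c,
        run_sd_clamped=clamped,
    )


def pool_rms(values: Sequence[float]) -> float:
    """Root mean square (quadratic mean) pooling of relative SDs."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot pool an empty list")
    if (v < 0).any():
        raise ValueError("relative SDs must be >= 0")
    return float(np.sqrt(np.mean(v**2)))


def bias_assessment(
    measured_means: Mapping[str, float],
    certified: Sequence[CertifiedLevel],
    u_precision_pooled_rel: float,
) -> BiasEstimate:
    """Relative bias per certified level, its mean and its uncertainty."""
    cert_by_id = {c.level_id: c for c in certified}
    missing = set(measured_means) - set(cert_by_id)
    if missing or not measured_means:
        raise ValueError(f"levels without certified values: {sorted(missing) or 'none measured'}")
    bias = {
        lid: (measured_means[lid] - cert_by_id[lid].c_cert) / cert_by_id[lid].c_cert
        for lid in measured_means
    }
    mean_bias = float(np.mean(list(bias.values())))
    used = [cert_by_id[lid] for lid in measured_means]
    u_bias = math.sqrt(
        u_precision_pooled_rel**2
        + sum(c.u_cert_rel**2 for c in used) / len(used)
    )
    U_bias = 2.0 * u_bias
    return BiasEstimate(
        bias_rel=bias,
        mean_bias_rel=mean_bias,
        u_bias_rel=u_bias,
        U_bias_rel=U_bias,
        significant=abs(mean_bias) > U_bias,
    )


def assay_variability(results_by_assay: Sequence[Sequence[float]]) -> float:
    """Between-assay relative SD from concentrations grouped per assay.

    One-way ANOVA with assays as groups; the component
    sqrt((MS_between − MS_within)/n_bar)/c_mean, clamped to zero when the
    between-assay mean square does not exceed the within-assay one.
    """
    if len(results_by_assay) < 2:
        raise ValueError("need at least 2 assay groups")
    a = one_way_anova(results_by_assay)
    if a.ms_between <= a.ms_within:
        return 0.0
    return math.sqrt((a.ms_between - a.ms_within) / a.n_bar) / abs(a.grand_mean)


def threshold_variability(
    per_replicate_variants: Sequence[Sequence[float]],
) -> float:
    """Relative SD attributable to the threshold setting.

    Each inner sequence holds one replicate's concentrations re-analysed
    under the different threshold variants (midpoint / low / high / rain
    removal).  Replicates are the ANOVA groups; the threshold component is
    sqrt(MS_within) divided by the overall mean concentration.
    """
    arrs = [np.asarray(g, dtype=float) for g in per_replicate_variants]
    if not arrs:
        raise ValueError("no replicates")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each replicate needs >= 2 threshold-variant results")
    n_total = sum(a.size for a in arrs)
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrs)
    ms_within = ss_within / (n_total - len(arrs))
    c = float(np.concatenate(arrs).mean())
    if c == 0:
        raise ValueError("zero mean concentration")
    return math.sqrt(ms_within) / abs(c)


def combined_uncertainty(
    s_repeat_rel: float,
    s_run_rel: float,
    u_vd_rel: float,
    u_bias_rel: float,
    *,
    n_meas: int,
    n_run: int = 1,
    s_thres_rel: float = 0.0,
    run_term: str = "variance",
) -> float:
    """Combined expanded relative measurement uncertainty (k = 2).

    ``run_term="variance"`` (default) divides the run variance by the
    number of runs (s_run²/n_run, consistent with the precision formula);
    ``"ratio"`` squares the ratio ((s_run/n_run)²) instead.  The two agree
    for n_run = 1.  ``s_thres_rel`` joins the quadrature only when the
    threshold contribution is non-negligible (working-range limits).
    """
    if n_meas < 1 or n_run < 1:
        raise ValueError("n_meas and n_run must be >= 1")
    for name, v in (
        ("s_repeat_rel", s_repeat_rel),
        ("s_run_rel", s_run_rel),
        ("u_vd_rel", u_vd_rel),
        ("u_bias_rel", u_bias_rel),
        ("s_thres_rel", s_thres_rel),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if run_term == "variance":
        run_sq = s_run_rel**2 / n_run
    elif run_term == "ratio":
        run_sq = (s_run_rel / n_run) ** 2
    else:
        raise ValueError("run_term must be 'variance' or 'ratio'")
    return 2.0 * math.sqrt(
        s_repeat_rel**2 / n_meas
        + run_sq
        + u_vd_rel**2
        + u_bias_rel**2
        + s_thres_rel**2
    )


def linearity_fit(
    expected: Sequence[float], measured: Sequence[float]
) -> tuple[float, float]:
    """Least-squares regression through the origin: slope and r².

    slope = Σxy/Σx²; r² = 1 − SS_res/SS_tot with the *uncentred* total sum
    of squares Σy², the convention appropriate for a no-intercept model.
    """
    x = np.asarray(expected, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.size < 1 or x.size != y.size:
        raise ValueError("expected and measured must be non-empty and equal length")
    if (x <= 0).any():
        raise ValueError("expected concentrations must be > 0")
    sxx = float((x * x).sum())
    slope = float((x * y).sum()) / sxx
    ss_res = float(((y - slope * x) ** 2).sum())
    ss_tot = float((y * y).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return slope, r2


LodSummary = namedtuple(
    "LodSummary", "n_valid n_positive mean_c_pcr rel_sd all_positive"
)


def lod_experimental(replicate_results: Sequence) -> LodSummary:
    """Summarise a low-level detection experiment.

    ``replicate_results`` are quantified :class:`~dropval.records.WellResult`
    objects measured at one low concentration; QC-failed wells are dropped.
    If every valid replicate shows at least one positive droplet, the
    tested concentration lies above the detection limit at the replicate
    count's confidence (60 all-positive replicates ≈ 95 %).
    """
    valid = [r for r in replicate_results if r.qc_passed]
    if not valid:
        raise ValueError("no valid replicates")
    n_pos = sum(1 for r in valid if r.P >= 1)
    concs = np.array([r.c_pcr for r in valid if r.c_pcr is not None], dtype=float)
    mean_c = float(concs.mean()) if concs.size else math.nan
    rel_sd = (
        float(concs.std(ddof=1) / abs(mean_c))
        if concs.size > 1 and mean_c != 0
        else math.nan
    )
    return LodSummary(
        n_valid=len(valid),
        n_positive=n_pos,
        mean_c_pcr=mean_c,
        rel_sd=rel_sd,
        all_positive=n_pos == len(valid),
    )


LoqAssessment = namedtuple(
    "LoqAssessment",
    "U_meas_rel meets_loq bias_rel U_bias_rel precision u_bias_rel",
)


def loq_assess(
    level_results: Sequence[Sequence[float]],
    certified: CertifiedLevel,
    *,
    u_vd_rel: float = 0.018,
    s_thres_rel: float = 0.0,
    n_meas: int = 4,
    acceptance_limit_rel: float = 0.30,
) -> LoqAssessment:
    """Quantification-limit check at one low level.

    ``level_results`` are the measured concentrations grouped per run
    (>= 2 runs).  Runs the precision analysis, the single-level bias
    assessment (n_cert = 1) and the combined uncertainty including the
    threshold term; the level qualifies as quantifiable when the expanded
    uncertainty of an ``n_meas``-replicate mean stays within the
    acceptance limit (30 % by default).
    """
    pe = precision_from_runs(level_results)
    bias_rel = (pe.mean_concentration - certified.c_cert) / certified.c_cert
    u_bias = math.sqrt(pe.u_precision_rel**2 + certified.u_cert_rel**2)
    U = combined_uncertainty(
        pe.s_repeat_rel,
        pe.s_run_rel,
        u_vd_rel,
        u_bias,
        n_meas=n_meas,
        n_run=1,
        s_thres_rel=s_thres_rel,
    )
    return LoqAssessment(
        U_meas_rel=U,
        meets_loq=U <= acceptance_limit_rel,
        bias_rel=bias_rel,
        U_bias_rel=2.0 * u_bias,
        precision=pe,
        u_bias_rel=u_bias,
    )


RobustnessRow = namedtuple(
    "RobustnessRow", "condition mean sd delta_vs_reference significant"
)


def robustness_compare(
    groups: Mapping[str, Sequence[float]],
    reference: str,
    U_meas_rel: float,
) -> list[RobustnessRow]:
    """Compare condition groups against the reference condition.

    A condition differs significantly when the relative deviation of its
    mean from the reference mean exceeds the method's expanded measurement
    uncertainty.
    """
    if reference not in groups:
        raise ValueError(f"reference condition {reference!r} not among groups")
    if any(len(v) == 0 for v in groups.values()):
        raise ValueError("empty condition group")
    ref_mean = float(np.mean(np.asarray(groups[reference], dtype=float)))
    rows = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        delta = (mean - ref_mean) / ref_mean
        rows.append(
            RobustnessRow(
                condition=name,
                mean=mean,
                sd=sd,
                delta_vs_reference=delta,
                significant=abs(delta) > U_meas_rel,
            )
        )
    return rows
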