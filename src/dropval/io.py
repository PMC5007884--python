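"""Plate file formats, study configuration and the validation pipeline.

Plates travel as plain CSV (UTF-8, header row, '.' decimal separator):
one row per well with counts and metadata, and an optional companion
amplitude file with one row per droplet (``well_id, amplitude``) for
workflows that keep the full fluorescence vectors.  Simulated plates are
written in the same dialect, with ground truth in a sidecar JSON.

:func:`run_validation` chains the whole analysis: QC → thresholding →
classification → quantification → per-level precision → RMS pooling →
bias against the certified levels → uncertainty budget → optional
LOD/LOQ.  Percentages appear only in the emitted report; internally all
relative quantities are fractions.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import reference
from .partitions import (
    ClusterStats,
    classify,
    estimate_clusters,
    make_thresholds,
    qc_well,
)
from .quantify import quantify_result
from .records import DropletWell, QCReport, WellResult
from .validation import (
    CertifiedLevel,
    UncertaintyBudget,
    assay_variability,
    bias_assessment,
    combined_uncertainty,
    lod_experimental,
    loq_assess,
    pool_rms,
    precision_from_runs,
)

logger = logging.getLogger("dropval")

__all__ = [
    "PLATE_COLUMNS",
    "StudyConfig",
    "read_plate",
    "write_plate",
    "run_validation",
]

PLATE_COLUMNS = [
    "well_id",
    "run_id",
    "level_id",
    "assay_id",
    "threshold_variant",
    "accepted",
    "positives",
    "df_sample",
    "df_pcr",
]

_REQUIRED = {"well_id", "accepted"}


def _fmt(x) -> str:
    if isinstance(x, float):
        if math.isnan(x):
            return ""
        return f"{x:.6g}"
    return "" if x is None else str(x)


def write_plate(
    wells: Sequence[DropletWell],
    path: Union[str, Path],
    amplitude_path: Optional[Union[str, Path]] = None,
    ground_truth_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write wells as a plate CSV (plus optional amplitude / truth files)."""
    rows = []
    for w in wells:
        rows.append(
            {
                "well_id": w.well_id,
                "run_id": w.run_id,
                "level_id": w.level_id,
                "assay_id": w.assay_id,
                "threshold_variant": w.threshold_variant,
                "accepted": w.accepted,
                "positives": "" if w.positives is None else w.positives,
                "df_sample": _fmt(w.df_sample),
                "df_pcr": _fmt(w.df_pcr),
            }
        )
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)

    if amplitude_path is not None:
        amp_rows = []
        for w in wells:
            if w.amplitudes is None:
                continue
            amp_rows.append(
                pd.DataFrame(
                    {"well_id": w.well_id, "amplitude": np.round(w.amplitudes, 4)}
                )
            )
        df = (
            pd.concat(amp_rows, ignore_index=True)
            if amp_rows
            else pd.DataFrame(columns=["well_id", "amplitude"])
        )
        df.to_csv(amplitude_path, index=False)

    if ground_truth_path is not None:
        truth = {
            w.well_id: {k: v for k, v in w.meta.items()} for w in wells if w.meta
        }
        Path(ground_truth_path).write_text(json.dumps(truth, indent=1, sort_keys=True))


def read_plate(
    path: Union[str, Path],
    amplitude_path: Optional[Union[str, Path]] = None,
) -> list[DropletWell]:
    """Read a plate CSV (tolerant of extra columns) into wells.

    Malformed rows raise with the offending well named; unknown columns
    only log a warning.  When an amplitude companion file is given, its
    vectors are attached to the matching wells and must agree with the
    accepted counts.
    """
    df = pd.read_csv(path)
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    unknown = set(df.columns) - set(PLATE_COLUMNS)
    if unknown:
        logger.warning("%s: ignoring unknown columns %s", path, sorted(unknown))
    if df["well_id"].duplicated().any():
        dupes = df.loc[df["well_id"].duplicated(), "well_id"].tolist()
        raise ValueError(f"{path}: duplicate well ids {dupes}")

    amps_by_well: dict[str, np.ndarray] = {}
    if amplitude_path is not None:
        adf = pd.read_csv(amplitude_path)
        if not {"well_id", "amplitude"} <= set(adf.columns):
            raise ValueError(f"{amplitude_path}: needs well_id and amplitude columns")
        for wid, grp in adf.groupby("well_id", sort=False):
            amps_by_well[str(wid)] = grp["amplitude"].to_numpy(dtype=float)
        orphan = set(amps_by_well) - set(df["well_id"].astype(str))
        if orphan:
            raise ValueError(
                f"{amplitude_path}: amplitudes for unknown wells {sorted(orphan)}"
            )

    def _get(row, col, default):
        if col not in df.columns or pd.isna(row[col]) or row[col] == "":
            return default
        return row[col]

    wells = []
    for i, row in df.iterrows():
        wid = str(row["well_id"])
        positives = _get(row, "positives", None)
        try:
            wells.append(
                DropletWell(
                    well_id=wid,
                    accepted=int(row["accepted"]),
                    amplitudes=amps_by_well.get(wid),
                    positives=None if positives is None else int(positives),
                    run_id=str(_get(row, "run_id", "run1")),
                    level_id=str(_get(row, "level_id", "")),
                    assay_id=str(_get(row, "assay_id", "")),
                    threshold_variant=str(_get(row, "threshold_variant", "midpoint")),
                    df_sample=float(_get(row, "df_sample", 1.0)),
                    df_pcr=float(_get(row, "df_pcr", 1.0)),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {i + 2} (well {wid}): {exc}") from exc
    return wells


@dataclass
class StudyConfig:
    """Everything the validation pipeline needs beyond the plates.

    Defaults reproduce the bundled study: ERM-AD623 certified levels,
    0.834 nL droplets with 1.8 % relative volume uncertainty, the three
    QC rules at their standard settings, automatic per-plate midpoint
    thresholding and a 30 % LOQ acceptance limit for a 4-replicate mean.
    """

    certified_levels: list[CertifiedLevel] = field(
        default_factory=lambda: list(reference.ERM_AD623)
    )
    droplet_volume_nl: float = reference.DROPLET_VOLUME_NL
    u_vd_rel: float = reference.DROPLET_VOLUME_REL_U
    min_droplets: int = 10_000
    tail_fraction: float = 0.05
    outlier_mad_multiple: float = 5.0
    threshold_mode: str = "auto"  # "auto" | "manual"
    manual_thresholds: dict[str, float] = field(default_factory=dict)
    loq_acceptance_rel: float = 0.30
    n_meas_report: int = 4
    n_run_report: int = 1
    s_thres_rel: float = 0.0
    lod_level_id: Optional[str] = None
    loq_level_id: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        levels = raw.pop("certified_levels", None)
        cfg = cls(**raw)
        if levels is not None:
            cfg.certified_levels = [
                CertifiedLevel(d["level_id"], d["c_cert"], d["u_cert"]) for d in levels
            ]
        return cfg

    def to_yaml(self, path: Union[str, Path]) -> None:
        d = dataclasses.asdict(self)
        d["certified_levels"] = [
            {"level_id": c.level_id, "c_cert": c.c_cert, "u_cert": c.u_cert}
            for c in self.certified_levels
        ]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _plate_threshold(
    config: StudyConfig, run_id: str, amp_wells: Sequence[DropletWell]
) -> tuple[float, Optional[ClusterStats]]:
    if config.threshold_mode == "manual":
        if run_id not in config.manual_thresholds:
            raise ValueError(f"no manual threshold configured for plate {run_id}")
        return config.manual_thresholds[run_id], None
    pooled = np.concatenate([w.amplitudes for w in amp_wells])
    clusters = estimate_clusters(pooled)
    if clusters.single_cluster:
        # blank plate: any threshold above the single cluster works
        return clusters.neg_mean + 8 * clusters.neg_sd + 1.0, clusters
    return make_thresholds(clusters).midpoint, clusters


def _classify_and_qc(
    config: StudyConfig, wells: Sequence[DropletWell]
) -> list[WellResult]:
    results: list[WellResult] = []
    by_plate: dict[str, list[DropletWell]] = {}
    for w in wells:
        by_plate.setdefault(w.run_id, []).append(w)
    for run_id, group in by_plate.items():
        amp_wells = [w for w in group if w.amplitudes is not None]
        thr = plate_clusters = None
        plate_stats: list[ClusterStats] = []
        if amp_wells:
            thr, plate_clusters = _plate_threshold(config, run_id, amp_wells)
            plate_stats = [estimate_clusters(w.amplitudes) for w in amp_wells]
        for w in group:
            if w.amplitudes is not None:
                res = classify(w, thr)
                qc = qc_well(
                    w,
                    plate_stats,
                    reference=plate_clusters
                    if plate_clusters is not None and not plate_clusters.single_cluster
                    else None,
                    min_droplets=config.min_droplets,
                    tail_fraction=config.tail_fraction,
                    outlier_mad_multiple=config.outlier_mad_multiple,
                )
            else:
                if w.positives is None:
                    raise ValueError(
                        f"well {w.well_id}: neither positives nor amplitudes"
                    )
                res = WellResult(
                    well_id=w.well_id,
                    P=w.positives,
                    A=w.accepted,
                    run_id=w.run_id,
                    level_id=w.level_id,
                    assay_id=w.assay_id,
                    threshold_variant=w.threshold_variant,
                    df_sample=w.df_sample,
                    df_pcr=w.df_pcr,
                )
                qc = qc_well(w, min_droplets=config.min_droplets)
            res.qc = qc
            res.droplet_volume_nl = config.droplet_volume_nl
            if not qc.passed:
                logger.info(
                    "well %s excluded: %s", w.well_id, ", ".join(qc.failed_rules)
                )
            quantify_result(res)
            results.append(res)
    return results


def run_validation(
    config: StudyConfig,
    plates: Union[Sequence[Union[str, Path]], Sequence[DropletWell]],
    out_dir: Optional[Union[str, Path]] = None,
    amplitude_paths: Optional[Sequence[Optional[Union[str, Path]]]] = None,
) -> dict:
    """Run the full validation analysis and (optionally) write report files.

    ``plates`` is either a list of plate CSV paths (with optional parallel
    ``amplitude_paths``) or an already-loaded list of wells.  Returns the
    report as a dict; with ``out_dir`` also writes ``report.json``,
    ``wells.csv`` and ``precision.csv``.
    """
    if len(plates) == 0:
        raise ValueError("no plates given")
    if isinstance(plates[0], DropletWell):
        wells = list(plates)
    else:
        wells = []
        for i, p in enumerate(plates):
            ap = amplitude_paths[i] if amplitude_paths else None
            wells.extend(read_plate(p, ap))

    results = _classify_and_qc(config, wells)
    passed = [r for r in results if r.qc_passed and not r.saturated]
    excluded = [r for r in results if not r.qc_passed]
    n_saturated = sum(1 for r in results if r.qc_passed and r.saturated)

    # ---- per-level precision over runs -----------------------------------
    level_ids = list(dict.fromkeys(r.level_id for r in passed))
    precision: dict[str, dict] = {}
    measured_means: dict[str, float] = {}
    for lid in level_ids:
        runs: dict[str, list[float]] = {}
        for r in passed:
            if r.level_id == lid:
                runs.setdefault(r.run_id, []).append(r.c_sample)
        if len(runs) < 2:
            logger.warning(
                "level %s measured in %d run(s); precision skipped", lid, len(runs)
            )
            continue
        pe = precision_from_runs(list(runs.values()))
        measured_means[lid] = pe.mean_concentration
        precision[lid] = {
            "c_meas": pe.mean_concentration,
            "s_repeat_rel": pe.s_repeat_rel,
            "s_run_rel": pe.s_run_rel,
            "u_precision_rel": pe.u_precision_rel,
            "n_runs": pe.n_runs,
            "n_bar_repli": pe.n_bar_repli,
            "run_sd_clamped": pe.run_sd_clamped,
        }

    report: dict = {
        "n_wells": len(results),
        "n_passed": len(passed),
        "n_excluded": len(excluded),
        "n_saturated": n_saturated,
        "excluded_wells": {
            r.well_id: list(r.qc.failed_rules) for r in excluded
        },
        "precision_per_level": precision,
    }

    if precision:
        s_rep_pool = pool_rms([d["s_repeat_rel"] for d in precision.values()])
        s_run_pool = pool_rms([d["s_run_rel"] for d in precision.values()])
        u_prec_pool = pool_rms([d["u_precision_rel"] for d in precision.values()])

        cert_ids = {c.level_id for c in config.certified_levels}
        bias_levels = {
            lid: m for lid, m in measured_means.items() if lid in cert_ids
        }
        bias = None
        u_bias = 0.0
        if bias_levels:
            bias = bias_assessment(
                bias_levels, config.certified_levels, u_prec_pool
            )
            u_bias = bias.u_bias_rel

        # between-assay component when two or more assays measured a level
        assay_components = []
        for lid in level_ids:
            by_assay: dict[str, list[float]] = {}
            for r in passed:
                if r.level_id == lid:
                    by_assay.setdefault(r.assay_id, []).append(r.c_sample)
            if len(by_assay) >= 2:
                assay_components.append(assay_variability(list(by_assay.values())))
        s_assay = pool_rms(assay_components) if assay_components else None

        U = combined_uncertainty(
            s_rep_pool,
            s_run_pool,
            config.u_vd_rel,
            u_bias,
            n_meas=config.n_meas_report,
            n_run=config.n_run_report,
            s_thres_rel=config.s_thres_rel,
        )
        budget = UncertaintyBudget(
            s_repeat_pooled_rel=s_rep_pool,
            s_run_pooled_rel=s_run_pool,
            u_precision_pooled_rel=u_prec_pool,
            u_vd_rel=config.u_vd_rel,
            u_bias_rel=u_bias,
            s_assay_rel=s_assay,
            s_thres_rel=config.s_thres_rel or None,
            n_meas=config.n_meas_report,
            n_runs=config.n_run_report,
            U_meas_rel=U,
        )
        report["budget_pct"] = {
            "s_repeat_pooled": 100 * budget.s_repeat_pooled_rel,
            "s_run_pooled": 100 * budget.s_run_pooled_rel,
            "u_precision_pooled": 100 * budget.u_precision_pooled_rel,
            "u_vd": 100 * budget.u_vd_rel,
            "u_bias": 100 * budget.u_bias_rel,
            "s_assay": None if s_assay is None else 100 * s_assay,
            "U_meas": 100 * budget.U_meas_rel,
            "n_meas": budget.n_meas,
            "n_runs": budget.n_runs,
        }
        if bias is not None:
            report["bias_pct"] = {
                "per_level": {k: 100 * v for k, v in bias.bias_rel.items()},
                "mean": 100 * bias.mean_bias_rel,
                "u_bias": 100 * bias.u_bias_rel,
                "U_bias": 100 * bias.U_bias_rel,
                "significant": bias.significant,
            }

    # ---- LOD / LOQ -------------------------------------------------------
    if config.lod_level_id is not None:
        lod_wells = [r for r in results if r.level_id == config.lod_level_id]
        if lod_wells:
            s = lod_experimental(lod_wells)
            report["lod"] = {
                "n_valid": s.n_valid,
                "n_positive": s.n_positive,
                "mean_c_pcr": s.mean_c_pcr,
                "rel_sd_pct": 100 * s.rel_sd if not math.isnan(s.rel_sd) else None,
                "all_positive": s.all_positive,
            }
    if config.loq_level_id is not None:
        cert = {c.level_id: c for c in config.certified_levels}.get(
            config.loq_level_id
        )
        runs = {}
        for r in passed:
            if r.level_id == config.loq_level_id:
                runs.setdefault(r.run_id, []).append(r.c_pcr)
        if cert is not None and len(runs) >= 2:
            la = loq_assess(
                list(runs.values()),
                cert,
                u_vd_rel=config.u_vd_rel,
                s_thres_rel=config.s_thres_rel,
                n_meas=config.n_meas_report,
                acceptance_limit_rel=config.loq_acceptance_rel,
            )
            report["loq"] = {
                "U_meas_pct": 100 * la.U_meas_rel,
                "meets_limit": la.meets_loq,
                "bias_pct": 100 * la.bias_rel,
                "U_bias_pct": 100 * la.U_bias_rel,
            }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        pd.DataFrame(
            [
                {
                    "well_id": r.well_id,
                    "run": r.run_id,
                    "level": r.level_id,
                    "assay": r.assay_id,
                    "variant": r.threshold_variant,
                    "P": r.P,
                    "A": r.A,
                    "rain": r.rain,
                    "threshold": _fmt(r.threshold),
                    "c_pcr": _fmt(r.c_pcr if r.c_pcr is not None else math.nan),
                    "c_sample": _fmt(r.c_sample if r.c_sample is not None else math.nan),
                    "qc_passed": r.qc_passed,
                    "failed_rules": ";".join(r.qc.failed_rules) if r.qc else "",
                }
                for r in results
            ]
        ).to_csv(out / "wells.csv", index=False)
        if precision:
            pd.DataFrame(
                [
                    {
                        "level": lid,
                        "c_meas": _fmt(d["c_meas"]),
                        "s_repeat_pct": _fmt(100 * d["s_repeat_rel"]),
                        "s_run_pct": _fmt(100 * d["s_run_rel"]),
                        "u_precision_pct": _fmt(100 * d["u_precision_rel"]),
                        "n_runs": d["n_runs"],
                    }
                    for lid, d in precision.items()
                ]
            ).to_csv(out / "precision.csv", index=False)
    return report
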