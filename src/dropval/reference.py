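"""Bundled reference data: ERM-AD623 certificate values and the published
single-laboratory validation summary of the BCR-ABL ddPCR method.

ERM-AD623 is a set of six solutions of a double-stranded linearized
plasmid carrying BCR, GUSB and BCR-ABL (b3a2) fragments, certified for
copy-number concentration by chip-based dPCR at three metrology
institutes.  The expanded uncertainties below are certificate values
(coverage factor k = 2).

The validation-summary tables are the per-level outputs of the in-house
validation campaign of the BCR-ABL droplet-dPCR method against these
materials; they serve as worked-example inputs for the pooling, bias and
uncertainty-budget arithmetic (the underlying ~200 raw well results were
never published, so re-deriving the per-level rows requires the
simulator).
"""
from __future__ import annotations

from .validation import CertifiedLevel

__all__ = [
    "ERM_AD623",
    "ACCURACY_STUDY",
    "THRESHOLD_STUDY",
    "ROBUSTNESS_STUDY",
    "SELECTIVITY_COUNTS",
    "LOQ_STUDY",
    "DROPLET_VOLUME_NL",
    "DROPLET_VOLUME_REL_U",
]

#: Assigned droplet volume (nL) and its relative standard uncertainty.
DROPLET_VOLUME_NL = 0.834
DROPLET_VOLUME_REL_U = 0.018

#: The six certified levels, copies/µL, expanded uncertainty k=2.
ERM_AD623 = [
    CertifiedLevel("AD623a", 1.08e6, 0.13e6),
    CertifiedLevel("AD623b", 1.08e5, 0.11e5),
    CertifiedLevel("AD623c", 1.03e4, 0.10e4),
    CertifiedLevel("AD623d", 1.02e3, 0.09e3),
    CertifiedLevel("AD623e", 1.04e2, 0.10e2),
    CertifiedLevel("AD623f", 10.0, 1.5),
]

#: Accuracy study (3 runs of 12/16/12 replicates per level): mean measured
#: sample concentration and per-level relative SDs (as fractions).
ACCURACY_STUDY = {
    "AD623a": {"c_meas": 0.97e6, "s_repeat_rel": 0.047, "s_run_rel": 0.014, "u_precision_rel": 0.011},
    "AD623b": {"c_meas": 0.93e5, "s_repeat_rel": 0.056, "s_run_rel": 0.053, "u_precision_rel": 0.032},
    "AD623c": {"c_meas": 0.94e4, "s_repeat_rel": 0.048, "s_run_rel": 0.027, "u_precision_rel": 0.018},
    "AD623d": {"c_meas": 0.93e3, "s_repeat_rel": 0.077, "s_run_rel": 0.0,   "u_precision_rel": 0.012},
    "AD623e": {"c_meas": 0.97e2, "s_repeat_rel": 0.073, "s_run_rel": 0.020, "u_precision_rel": 0.016},
}

#: Threshold-setting study at five PCR concentrations: average droplet
#: composition per measurement and the threshold-variability component.
THRESHOLD_STUDY = [
    {"c_pcr_exp": 5400.0, "pos": 18046, "neg": 414,   "rain": 95.9, "s_thres_rel": 0.030},
    {"c_pcr_exp": 2575.0, "pos": 16005, "neg": 2530,  "rain": 39.0, "s_thres_rel": 0.005},
    {"c_pcr_exp": 255.0,  "pos": 3488,  "neg": 16248, "rain": 14.3, "s_thres_rel": 0.003},
    {"c_pcr_exp": 26.0,   "pos": 397,   "neg": 19457, "rain": 4.1,  "s_thres_rel": 0.008},
    {"c_pcr_exp": 2.5,    "pos": 38,    "neg": 19708, "rain": 3.6,  "s_thres_rel": 0.072},
]

#: Selectivity: pooled droplet counts from 4 matrix-blank and 4
#: positive-control (54,000 cp/µL) replicates at the midpoint threshold.
SELECTIVITY_COUNTS = {
    "blank_positive_droplets": 0,
    "blank_accepted_droplets": 61_275,
    "control_negative_droplets": 33,
    "control_accepted_droplets": 57_895,
}

#: Quantification-limit study at 3.50 cp/µL in the PCR mix (2 runs,
#: 23 valid of 24 replicates).  ``u_precision_rel`` is the published
#: value, which is not reproducible from the published s_repeat/s_run via
#: the precision formula; it is carried as an input.
LOQ_STUDY = {
    "c_pcr_exp": 3.50,
    "c_pcr_meas": 3.35,
    "n_valid": 23,
    "n_runs": 2,
    "s_repeat_rel": 0.170,
    "s_run_rel": 0.0,
    "u_precision_rel": 0.050,
    "s_thres_rel": 0.072,
    "u_cert_rel": (1.5 / 2) / 10.0,
    "n_meas": 4,
    "acceptance_limit_rel": 0.30,
}

#: Robustness: mean ± SD of the measured PCR concentration under small
#: deliberate changes of primers/probe concentration (at ~310 cp/µL) and
#: annealing temperature (at ~3200 cp/µL).  First entry of each block is
#: the reference condition.
ROBUSTNESS_STUDY = {
    "primers_probe": {
        "optimal": (279.0, 5.0),
        "plus10pct": (273.0, 4.0),
        "minus10pct": (285.0, 8.0),
    },
    "annealing": {
        "60C": (2954.0, 35.0),
        "59C": (2946.0, 54.0),
        "61C": (2948.0, 68.0),
    },
}
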