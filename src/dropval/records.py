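"""Core record types shared across the pipeline.

A :class:`DropletWell` is the atomic measurement: one well's droplet
fluorescence amplitudes (or, when the instrument export carries only
summary counts, the positive/accepted droplet counts) together with the
plate metadata needed downstream. A :class:`WellResult` is what
classification and quantification produce from it: counts under a given
threshold, QC status and the absolute copy-number concentration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["DropletWell", "WellResult", "QCReport"]


@dataclass
class QCReport:
    """Outcome of the three technical well-exclusion rules.

    ``failed_rules`` is a subset of ``{"min_droplets", "amplitude_outlier",
    "low_amplitude_tail"}``; ``passed`` is true iff it is empty.  ``details``
    carries per-rule diagnostics (the measured count / fraction / robust z,
    or ``"not evaluated"`` when amplitudes were unavailable).
    """

    passed: bool
    failed_rules: tuple[str, ...] = ()
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.passed != (len(self.failed_rules) == 0):
            raise ValueError("passed must be equivalent to failed_rules being empty")


@dataclass
class DropletWell:
    """One well of a droplet digital PCR plate.

    Parameters
    ----------
    well_id : str
        Plate coordinate (e.g. ``"A01"``).
    accepted : int
        Number of droplets passing the instrument's read quality gating.
    amplitudes : ndarray, optional
        Fluorescence amplitude per accepted droplet.  When present its
        length must equal ``accepted``.
    positives : int, optional
        Positive-droplet count; may be omitted when amplitudes are present
        (classification then derives it from a threshold).
    df_sample, df_pcr : float
        Dilution factor of the DNA sample before the PCR mix, and of the
        sample within the PCR mix.  Both dimensionless and >= 1.
    meta : dict
        Free-form metadata; the simulator records ground truth here
        (true concentration, true positive count, injected rain count).
    """

    well_id: str
    accepted: int
    amplitudes: Optional[np.ndarray] = None
    positives: Optional[int] = None
    run_id: str = "run1"
    level_id: str = ""
    assay_id: str = ""
    threshold_variant: str = "midpoint"
    df_sample: float = 1.0
    df_pcr: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accepted = int(self.accepted)
        if self.accepted < 0:
            raise ValueError(f"accepted droplets must be >= 0, got {self.accepted}")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if self.amplitudes.ndim != 1:
                raise ValueError("amplitudes must be a 1-D vector")
            if self.amplitudes.size != self.accepted:
                raise ValueError(
                    f"well {self.well_id}: {self.amplitudes.size} amplitudes "
                    f"but accepted={self.accepted}"
                )
        if self.positives is not None:
            self.positives = int(self.positives)
            if not 0 <= self.positives <= self.accepted:
                raise ValueError(
                    f"well {self.well_id}: positives={self.positives} outside "
                    f"[0, {self.accepted}]"
                )
        for name, df in (("df_sample", self.df_sample), ("df_pcr", self.df_pcr)):
            if df < 1.0:
                raise ValueError(f"{name} must be >= 1, got {df}")


@dataclass
class WellResult:
    """Classified counts and computed concentration for one well.

    ``c_pcr`` is the copy-number concentration in the PCR mix (copies/µL)
    and ``c_sample = df_sample * df_pcr * c_pcr`` the concentration in the
    undiluted sample.  Both are ``None`` before quantification and ``nan``
    (with ``saturated=True``) when every droplet is positive, in which case
    the Poisson estimate is unbounded.
    """

    well_id: str
    P: int
    A: int
    rain: int = 0
    threshold: float = math.nan
    run_id: str = "run1"
    level_id: str = ""
    assay_id: str = ""
    threshold_variant: str = "midpoint"
    df_sample: float = 1.0
    df_pcr: float = 1.0
    droplet_volume_nl: float = 0.834
    c_pcr: Optional[float] = None
    c_sample: Optional[float] = None
    saturated: bool = False
    qc: Optional[QCReport] = None

    def __post_init__(self) -> None:
        if not 0 <= self.P <= self.A:
            raise ValueError(f"well {self.well_id}: P={self.P} outside [0, A={self.A}]")
        if self.rain < 0:
            raise ValueError("rain count must be >= 0")

    @property
    def qc_passed(self) -> bool:
        return self.qc is None or self.qc.passed
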