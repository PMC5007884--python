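"""Absolute quantification from partition counts.

The estimator inverts the Poisson occupancy of the droplets.  With ``A``
analysed droplets of volume ``Vd`` and ``P`` of them positive, the number
of target copies present in the analysed droplets is estimated as

    copies = ln(1 - P/A) / ln(1 - 1/A)

and the concentration in the PCR mix follows by dividing by the analysed
volume ``A * Vd``.  The exact form accounts for the finite number of
partitions; for ``A >= 1e4`` it agrees with the familiar approximation
``c = -ln(1 - P/A) / Vd`` to better than 0.01 % relative.  Natural
logarithms are used throughout (any common base cancels in the ratio, but
the approximation identity above holds only for ln).

Dilution factors are handled gravimetrically: all preparations are weighed
and converted to volumes through the component densities, which removes
pipetting uncertainty from the budget.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .records import WellResult

__all__ = [
    "SaturationError",
    "concentration_from_counts",
    "GravimetricRecord",
    "gravimetric_dilution_factor",
    "quantify_result",
]

#: Nominal droplet volume in nanolitres for the QX100 emulsion system.
DEFAULT_DROPLET_VOLUME_NL = 0.834


class SaturationError(ValueError):
    """Every droplet is positive; the Poisson estimate is unbounded."""


def concentration_from_counts(
    P: int,
    A: int,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    df_sample: float = 1.0,
    df_pcr: float = 1.0,
) -> tuple[float, float]:
    """Concentration in the PCR mix and in the undiluted sample, copies/µL.

    Parameters
    ----------
    P, A : int
        Positive and accepted (analysed) droplet counts, ``0 <= P < A``.
    droplet_volume_nl : float
        Droplet volume in nanolitres (converted internally to µL).
    df_sample, df_pcr : float
        Dilution factors, both >= 1.

    Returns
    -------
    (c_pcr, c_sample) : tuple of float
        ``c_sample = df_sample * df_pcr * c_pcr``.

    Raises
    ------
    SaturationError
        If ``P == A`` (all droplets positive).
    ValueError
        For P > A, A < 2 or non-positive droplet volume.
    """
    if A < 2:
        raise ValueError(f"need at least 2 accepted droplets, got A={A}")
    if P < 0 or P > A:
        raise ValueError(f"P={P} outside [0, A={A}]")
    if P == A:
        raise SaturationError(
            f"all {A} droplets positive: concentration not quantifiable"
        )
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    if df_sample < 1 or df_pcr < 1:
        raise ValueError("dilution factors must be >= 1")
    # log1p keeps precision for the tiny 1/A term
    copies = math.log1p(-P / A) / math.log1p(-1.0 / A)
    vd_ul = droplet_volume_nl * 1e-3
    c_pcr = copies / (A * vd_ul)
    return c_pcr, df_sample * df_pcr * c_pcr


@dataclass
class GravimetricRecord:
    """Masses weighed during one dilution / mix-preparation step.

    The sample aliquot (mass ``mass_sample_g``) is combined with buffer
    diluent and/or the pre-sample PCR mix; densities convert masses to
    volumes.  The default pre-mix density 1.0353 g/mL is the measured
    density of the probe supermix; buffer and sample default to 1 g/mL.
    """

    mass_sample_g: float
    mass_diluent_g: float = 0.0
    mass_premix_g: float = 0.0
    density_sample_g_per_ml: float = 1.0
    density_diluent_g_per_ml: float = 1.0
    density_premix_g_per_ml: float = 1.0353

    def __post_init__(self) -> None:
        if self.mass_sample_g <= 0:
            raise ValueError("sample mass must be positive")
        if self.mass_diluent_g < 0 or self.mass_premix_g < 0:
            raise ValueError("masses must be non-negative")
        for d in (
            self.density_sample_g_per_ml,
            self.density_diluent_g_per_ml,
            self.density_premix_g_per_ml,
        ):
            if d <= 0:
                raise ValueError("densities must be positive")


def gravimetric_dilution_factor(record: GravimetricRecord) -> float:
    """Dilution factor of one gravimetric preparation step.

    ``df = V_total / V_sample`` with volumes obtained from the weighed
    masses and densities.  For a PCR-mix step (sample + pre-mix) this is
    ``(V_sample + V_premix) / V_sample``; chain multiple steps by
    multiplying their factors.
    """
    v_sample = record.mass_sample_g / record.density_sample_g_per_ml
    v_diluent = record.mass_diluent_g / record.density_diluent_g_per_ml
    v_premix = record.mass_premix_g / record.density_premix_g_per_ml
    return (v_sample + v_diluent + v_premix) / v_sample


def quantify_result(result: WellResult) -> WellResult:
    """Fill ``c_pcr``/``c_sample`` on a classified :class:`WellResult` in place.

    Saturated wells (``P == A``) get ``nan`` concentrations and the
    ``saturated`` flag instead of an exception, so plate-level pipelines
    can keep going and report the well.
    """
    if result.P == result.A:
        result.saturated = True
        result.c_pcr = math.nan
        result.c_sample = math.nan
        return result
    c_pcr, c_sample = concentration_from_counts(
        result.P,
        result.A,
        droplet_volume_nl=result.droplet_volume_nl,
        df_sample=result.df_sample,
        df_pcr=result.df_pcr,
    )
    result.c_pcr = c_pcr
    result.c_sample = c_sample
    return result
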