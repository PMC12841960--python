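"""Spectrophotometric quantification of plasma free hemoglobin.

The Harboe method measures free hemoglobin directly from plasma absorbance
at 380, 415 and 450 nm.  The 415 nm reading sits on the oxyhemoglobin Soret
peak; the flanking 380/450 nm readings form an Allen-type baseline
correction that removes linearly varying background (e.g. moderate
bilirubin staining or turbidity):

    fHb (mg/L) = 836 * (2 * A415 - A380 - A450)

Biochemistry analyzers report semiquantitative serum indices for hemolysis,
icterus and lipemia (HIL).  This module also converts the hemolysis index
into an estimated free hemoglobin concentration (efHb) and the icterus
index into an estimated total bilirubin, using analyzer-specific
proportionality factors.  The defaults correspond to one widely deployed
clinical chemistry platform (1 H unit ~ 10 mg/L fHb, 1 I unit ~ 69 umol/L
total bilirubin) and must be re-validated on any other analyzer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HARBOE_COEFFICIENT",
    "DEFAULT_H_TO_FHB_FACTOR",
    "DEFAULT_I_TO_TBIL_FACTOR",
    "ABSORBANCE_LINEAR_MAX",
    "AbsorbanceTriplet",
    "HILIndices",
    "FhbResult",
    "compute_fhb",
    "efhb_from_h_index",
    "etbil_from_i_index",
    "convert_fhb_units",
]

#: Harboe coefficient, mg/L per absorbance unit of the corrected Soret term.
HARBOE_COEFFICIENT = 836.0

#: mg/L of free hemoglobin per unit of the analyzer hemolysis index.
DEFAULT_H_TO_FHB_FACTOR = 10.0

#: umol/L of total bilirubin per unit of the analyzer icterus index.
DEFAULT_I_TO_TBIL_FACTOR = 69.0

#: Absorbance above which a reading is flagged as beyond the photometric
#: range typical of laboratory spectrophotometers.  Readings this high are
#: still computed but the result carries ``out_of_range=True``.
ABSORBANCE_LINEAR_MAX = 2.5


def _require_nonnegative_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class AbsorbanceTriplet:
    """Raw absorbance readings at the three Harboe wavelengths (AU)."""

    a380: float
    a415: float
    a450: float

    def __post_init__(self) -> None:
        for name in ("a380", "a415", "a450"):
            object.__setattr__(
                self, name, _require_nonnegative_finite(name, getattr(self, name))
            )

    @property
    def out_of_range(self) -> bool:
        """True when any reading exceeds the typical photometric range."""
        return max(self.a380, self.a415, self.a450) > ABSORBANCE_LINEAR_MAX


@dataclass(frozen=True)
class HILIndices:
    """Analyzer serum indices for hemolysis, icterus and lipemia.

    Dimensionless, analyzer-specific units; all must be finite and >= 0.
    """

    h_index: float
    i_index: float
    l_index: float = 0.0

    def __post_init__(self) -> None:
        for name in ("h_index", "i_index", "l_index"):
            object.__setattr__(
                self, name, _require_nonnegative_finite(name, getattr(self, name))
            )


@dataclass(frozen=True)
class FhbResult:
    """Harboe free-hemoglobin result with quality flags.

    ``clamped`` marks a raw formula value below zero (blank-level noise)
    that was floored at 0; ``out_of_range`` marks any absorbance beyond the
    typical photometric range.
    """

    value: float
    clamped: bool = False
    out_of_range: bool = False


def compute_fhb(triplet: AbsorbanceTriplet) -> FhbResult:
    """Compute free hemoglobin (mg/L) from a Harboe absorbance triplet.

    Negative raw values are physically meaningless readings near the blank
    and are clamped to 0 with ``clamped=True`` so that batch processing
    remains total.

    >>> compute_fhb(AbsorbanceTriplet(a380=0.5, a415=1.0, a450=0.5)).value
    836.0
    """
    raw = HARBOE_COEFFICIENT * (2.0 * triplet.a415 - triplet.a380 - triplet.a450)
    clamped = raw < 0.0
    return FhbResult(
        value=max(0.0, raw),
        clamped=clamped,
        out_of_range=triplet.out_of_range,
    )


def efhb_from_h_index(
    h_index: float, factor: float = DEFAULT_H_TO_FHB_FACTOR
) -> float:
    """Estimate free hemoglobin (mg/L) from the analyzer hemolysis index."""
    h_index = _require_nonnegative_finite("h_index", h_index)
    if not factor > 0:
        raise ValueError(f"factor must be > 0, got {factor!r}")
    return h_index * factor


def etbil_from_i_index(
    i_index: float, factor: float = DEFAULT_I_TO_TBIL_FACTOR
) -> float:
    """Estimate total bilirubin (umol/L) from the analyzer icterus index."""
    i_index = _require_nonnegative_finite("i_index", i_index)
    if not factor > 0:
        raise ValueError(f"factor must be > 0, got {factor!r}")
    return i_index * factor


def convert_fhb_units(value_mg_l: float) -> float:
    """Convert a free-hemoglobin concentration from mg/L to mg/dL.

    Extracorporeal-support guidelines state their investigation threshold
    in mg/dL (50 mg/dL = 500 mg/L); all file interfaces in this package use
    mg/L, so conversion is always explicit.
    """
    value_mg_l = _require_nonnegative_finite("value_mg_l", value_mg_l)
    return value_mg_l / 10.0
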