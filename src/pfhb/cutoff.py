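"""Empirical bilirubin cut-off for Harboe-method interference.

The disagreement between Harboe-measured fHb and index-estimated efHb
grows with bilirubin.  This module locates the bilirubin concentration
above which the relative inter-method difference becomes clinically
significant, by:

1. computing per-sample deltas (fHb - efHb) and relative deltas
   |delta| / fHb (the Harboe value is the designated reference method and
   therefore the denominator);
2. sorting samples by bilirubin and smoothing the relative delta with a
   centered rolling median (edge windows truncated);
3. declaring the cut-off at the smallest bilirubin whose smoothed relative
   delta exceeds the threshold *and stays above it for all larger
   bilirubin values* (one-sided persistence), with the additional
   requirement that the persistent region contain at least ``window``
   points so that a handful of noisy extreme-bilirubin samples cannot
   fabricate a changepoint.

The same procedure applies to total or conjugated bilirubin by passing the
corresponding concentration as the bilirubin axis.  The procedure is
descriptive by design; it performs no formal changepoint inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .comparison import EstimationError

__all__ = ["DeltaPoint", "CutoffResult", "compute_deltas", "derive_cutoff"]

DEFAULT_REL_THRESHOLD = 0.5
DEFAULT_WINDOW = 7


@dataclass(frozen=True)
class DeltaPoint:
    """Per-sample method disagreement at a given bilirubin level.

    ``rel_delta`` is |fhb - efhb| / fhb and is undefined (None) when
    fhb = 0; such points are excluded from cut-off derivation.
    """

    bilirubin: float  # umol/L (tBil or dBil)
    fhb: float  # mg/L, Harboe (reference)
    efhb: float  # mg/L, index estimate
    delta: float  # mg/L, fhb - efhb
    rel_delta: Optional[float]


@dataclass(frozen=True)
class CutoffResult:
    """Detected interference cut-off with the smoothed exceedance trace."""

    cutoff: Optional[float]  # umol/L; None when no persistent exceedance
    analyte: str  # "tBil" or "dBil"
    window: int
    rel_threshold: float
    n_points: int
    trace: tuple[tuple[float, float], ...]  # (bilirubin, rolling median rel_delta)

    @property
    def detected(self) -> bool:
        return self.cutoff is not None


def compute_deltas(
    samples: Iterable[tuple[float, float, float]]
) -> list[DeltaPoint]:
    """Per-sample deltas from (bilirubin, fhb, efhb) triples."""
    points: list[DeltaPoint] = []
    for row, (bil, fhb, efhb) in enumerate(samples, start=1):
        for name, v in (("bilirubin", bil), ("fhb", fhb), ("efhb", efhb)):
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(
                    f"row {row}: {name} must be finite and >= 0, got {v!r}"
                )
        delta = fhb - efhb
        rel = abs(delta) / fhb if fhb > 0 else None
        points.append(DeltaPoint(bil, fhb, efhb, delta, rel))
    if not points:
        raise ValueError("empty input: no samples")
    return points


def derive_cutoff(
    points: Sequence[DeltaPoint],
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    window: int = DEFAULT_WINDOW,
    analyte: str = "tBil",
) -> CutoffResult:
    """Locate the bilirubin level where relative disagreement exceeds the
    threshold and persists.

    Requires at least ``window`` points with defined relative delta.
    Returns ``cutoff=None`` when the smoothed relative delta never shows a
    persistent, sufficiently supported exceedance.
    """
    if not (0 < rel_threshold <= 1):
        raise ValueError(f"rel_threshold must be in (0, 1], got {rel_threshold!r}")
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window!r}")
    usable = [p for p in points if p.rel_delta is not None]
    if len(usable) < window:
        raise EstimationError(
            f"need at least window={window} points with defined rel_delta, "
            f"got {len(usable)}"
        )
    order = sorted(range(len(usable)), key=lambda k: usable[k].bilirubin)
    bil = np.array([usable[k].bilirubin for k in order])
    rel = np.array([usable[k].rel_delta for k in order])

    smoothed = (
        pd.Series(rel).rolling(window, center=True, min_periods=1).median().to_numpy()
    )
    exceed = smoothed > rel_threshold
    # Persistence: keep only indices from which exceedance holds to the end.
    persistent = np.logical_and.accumulate(exceed[::-1])[::-1]
    idx = np.flatnonzero(persistent)

    cutoff = None
    if len(idx) >= window:  # minimum support for the changepoint
        cutoff = float(bil[idx[0]])
    return CutoffResult(
        cutoff=cutoff,
        analyte=analyte,
        window=window,
        rel_threshold=rel_threshold,
        n_points=len(usable),
        trace=tuple(zip(bil.tolist(), smoothed.tolist())),
    )
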