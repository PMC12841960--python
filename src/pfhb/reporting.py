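"""Interference-aware reporting rules for plasma free hemoglobin results.

Free hemoglobin measured by the Harboe method is vulnerable to icteric and
lipemic interference, and to in-vitro hemolysis introduced during sampling.
This module implements a four-step autoverification algorithm that a
clinical laboratory applies before releasing an fHb result:

1. *Icterus*: an icterus index above its trigger demands a total-bilirubin
   measurement; at tBil >= the restriction threshold the Harboe result is
   released only on explicit clinician request (re-sampling is pointless,
   since the icterus reflects the patient, not the sample).
2. *Hemolysis index*: a high hemolysis index with unverified venipuncture
   points to a possible preanalytical error and blocks release until the
   sampling is verified.
3. *Lipemia*: if the lipemia source (parenteral nutrition, propofol
   sedation) can be paused, a new sample is requested; otherwise a low fHb
   may be released with a LIPEMIC_SAMPLE annotation, while a high fHb goes
   to clinician-request-only release.
4. *Severe hemolysis*: a very high fHb with unremarkable bilirubin and
   unverified venipuncture triggers a sampling review before release.

Every numeric threshold lives in :class:`ThresholdConfig` because serum
indices are analyzer-specific: each laboratory must establish its own
values against paired spectrophotometric measurements.

The decision function is total and pure: every valid record maps to
exactly one status, and the full ordered rule trace is returned so the
laboratory can document why a result was or was not released.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Any, Iterable, Mapping, Optional, Sequence

from .measurement import (
    DEFAULT_H_TO_FHB_FACTOR,
    DEFAULT_I_TO_TBIL_FACTOR,
    HILIndices,
)

__all__ = [
    "ReportStatus",
    "Annotation",
    "SampleRecord",
    "ThresholdConfig",
    "RuleFire",
    "ReportDecision",
    "decide",
    "decide_batch",
]

logger = logging.getLogger(__name__)


class ReportStatus(str, Enum):
    """Terminal verdicts of the reporting algorithm."""

    REPORT = "REPORT"
    REPORT_WITH_ANNOTATION = "REPORT_WITH_ANNOTATION"
    CLINICIAN_REQUEST_ONLY = "CLINICIAN_REQUEST_ONLY"
    REQUEST_NEW_SAMPLE = "REQUEST_NEW_SAMPLE"
    VERIFY_PREANALYTICS = "VERIFY_PREANALYTICS"
    NEEDS_TBIL = "NEEDS_TBIL"


class Annotation(str, Enum):
    """Comment codes attached to released or withheld results."""

    LIPEMIC_SAMPLE = "LIPEMIC_SAMPLE"
    ICTERIC_INTERFERENCE = "ICTERIC_INTERFERENCE"
    REVIEW_SAMPLING = "REVIEW_SAMPLING"


def _check_conc(name: str, value: Optional[float]) -> Optional[float]:
    if value is None:
        return None
    value = float(value)
    if not math.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be finite and >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class SampleRecord:
    """One patient sample with its indices, concentrations and context.

    Concentrations are optional until measured (``None``); when both
    bilirubin fractions are present, conjugated (dbil) cannot exceed total
    (tbil).
    """

    sample_id: str
    hil: HILIndices
    fhb: Optional[float] = None  # mg/L, Harboe
    tbil: Optional[float] = None  # umol/L, total bilirubin
    dbil: Optional[float] = None  # umol/L, conjugated (direct) bilirubin
    lipemia_present: bool = False
    parenteral_nutrition: bool = False
    nutrition_discontinuable: bool = False
    propofol_sedation: bool = False
    sedation_adjustable: bool = False
    venipuncture_verified: bool = False
    clinician_requested: bool = False

    def __post_init__(self) -> None:
        for name in ("fhb", "tbil", "dbil"):
            object.__setattr__(self, name, _check_conc(name, getattr(self, name)))
        if self.dbil is not None and self.tbil is not None and self.dbil > self.tbil:
            raise ValueError(
                f"sample {self.sample_id!r}: dbil ({self.dbil}) > tbil ({self.tbil})"
            )


@dataclass(frozen=True)
class ThresholdConfig:
    """All numeric thresholds of the reporting algorithm.

    Defaults reflect one analyzer platform; serum-index behavior is
    analyzer-specific, so laboratories must set their own values.

    Strictness follows the algorithm's wording: index and fHb triggers are
    strict (``exceeds``), the bilirubin restriction is inclusive
    (``equal to or greater``), and ceilings are strict (``below``).
    """

    icterus_trigger: float = 4.0  # analyzer units, strict >
    tbil_restrict: float = 75.0  # umol/L, inclusive >=
    h_trigger: float = 10.0  # analyzer units, strict >
    fhb_review: float = 200.0  # mg/L, strict >
    tbil_review_ceiling: float = 100.0  # umol/L, strict <
    lipemic_report_max: float = 50.0  # mg/L, strict <
    h_to_fhb_factor: float = DEFAULT_H_TO_FHB_FACTOR
    i_to_tbil_factor: float = DEFAULT_I_TO_TBIL_FACTOR
    rel_delta_threshold: float = 0.5  # fraction, for cut-off derivation

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{f.name} must be positive and finite, got {v!r}")
        if not (0 < self.rel_delta_threshold <= 1):
            raise ValueError(
                f"rel_delta_threshold must be in (0, 1], got {self.rel_delta_threshold!r}"
            )


@dataclass(frozen=True)
class RuleFire:
    """One entry of the ordered rule trace."""

    rule_id: str
    fired: bool
    inputs: Mapping[str, Any] = field(default_factory=dict)


@dataclass(frozen=True)
class ReportDecision:
    """The engine's verdict for one sample."""

    sample_id: str
    status: ReportStatus
    annotations: tuple[str, ...] = ()
    rule_trace: tuple[RuleFire, ...] = ()


def _need_fhb(record: SampleRecord, rule_id: str) -> float:
    if record.fhb is None:
        raise ValueError(
            f"rule {rule_id!r} requires a measured fhb but none is present"
        )
    return record.fhb


def decide(record: SampleRecord, cfg: ThresholdConfig | None = None) -> ReportDecision:
    """Run the four-step reporting algorithm on one sample.

    Rules are evaluated in order; the first blocking rule terminates
    evaluation, while non-blocking annotations (e.g. icteric interference
    acknowledged by a clinician request) accumulate onto the final status.
    """
    if cfg is None:
        cfg = ThresholdConfig()
    trace: list[RuleFire] = []
    annotations: list[str] = []

    def finish(status: ReportStatus) -> ReportDecision:
        decision = ReportDecision(
            sample_id=record.sample_id,
            status=status,
            annotations=tuple(annotations),
            rule_trace=tuple(trace),
        )
        logger.info(
            "sample %s -> %s%s",
            record.sample_id,
            status.value,
            f" [{', '.join(annotations)}]" if annotations else "",
        )
        return decision

    # Step 1: icterus interference.  Re-sampling is never recommended here:
    # the icterus index reflects the patient's bilirubin, not the sample.
    icterus_fired = record.hil.i_index > cfg.icterus_trigger
    trace.append(
        RuleFire(
            "icterus_index_trigger",
            icterus_fired,
            {"i_index": record.hil.i_index, "icterus_trigger": cfg.icterus_trigger},
        )
    )
    if icterus_fired:
        if record.tbil is None:
            trace.append(RuleFire("icterus_tbil_reflex", True, {"tbil": None}))
            return finish(ReportStatus.NEEDS_TBIL)
        restrict_fired = record.tbil >= cfg.tbil_restrict
        trace.append(
            RuleFire(
                "icterus_tbil_restrict",
                restrict_fired,
                {
                    "tbil": record.tbil,
                    "tbil_restrict": cfg.tbil_restrict,
                    "clinician_requested": record.clinician_requested,
                },
            )
        )
        if restrict_fired:
            annotations.append(Annotation.ICTERIC_INTERFERENCE.value)
            if not record.clinician_requested:
                return finish(ReportStatus.CLINICIAN_REQUEST_ONLY)
            # Clinician already aware: continue with the annotation attached.

    # Step 2: hemolysis index vs preanalytics.
    hemolysis_fired = (
        record.hil.h_index > cfg.h_trigger and not record.venipuncture_verified
    )
    trace.append(
        RuleFire(
            "hemolysis_verify_sampling",
            hemolysis_fired,
            {
                "h_index": record.hil.h_index,
                "h_trigger": cfg.h_trigger,
                "venipuncture_verified": record.venipuncture_verified,
            },
        )
    )
    if hemolysis_fired:
        return finish(ReportStatus.VERIFY_PREANALYTICS)

    # Step 3: lipemia.
    if record.lipemia_present:
        removable = (record.parenteral_nutrition and record.nutrition_discontinuable) or (
            record.propofol_sedation and record.sedation_adjustable
        )
        trace.append(
            RuleFire(
                "lipemia_resample",
                removable,
                {
                    "parenteral_nutrition": record.parenteral_nutrition,
                    "nutrition_discontinuable": record.nutrition_discontinuable,
                    "propofol_sedation": record.propofol_sedation,
                    "sedation_adjustable": record.sedation_adjustable,
                },
            )
        )
        if removable:
            return finish(ReportStatus.REQUEST_NEW_SAMPLE)
        fhb = _need_fhb(record, "lipemia_report")
        low_enough = fhb < cfg.lipemic_report_max
        trace.append(
            RuleFire(
                "lipemia_report",
                True,
                {"fhb": fhb, "lipemic_report_max": cfg.lipemic_report_max},
            )
        )
        annotations.append(Annotation.LIPEMIC_SAMPLE.value)
        if low_enough:
            return finish(ReportStatus.REPORT_WITH_ANNOTATION)
        # High fHb on an unremovable lipemic background: conservative route,
        # release only after direct communication with the clinician.
        return finish(ReportStatus.CLINICIAN_REQUEST_ONLY)
    trace.append(RuleFire("lipemia_resample", False, {"lipemia_present": False}))

    # Step 4: severe hemolysis review.
    fhb = _need_fhb(record, "severe_hemolysis_review")
    if fhb > cfg.fhb_review and record.tbil is None:
        # The rule compares against tBil, which was never measured because
        # the icterus index stayed below its trigger: demand the reflex test.
        trace.append(
            RuleFire(
                "severe_hemolysis_review",
                True,
                {"fhb": fhb, "fhb_review": cfg.fhb_review, "tbil": None},
            )
        )
        return finish(ReportStatus.NEEDS_TBIL)
    review_fired = (
        fhb > cfg.fhb_review
        and record.tbil is not None
        and record.tbil < cfg.tbil_review_ceiling
        and not record.venipuncture_verified
    )
    trace.append(
        RuleFire(
            "severe_hemolysis_review",
            review_fired,
            {
                "fhb": fhb,
                "fhb_review": cfg.fhb_review,
                "tbil": record.tbil,
                "tbil_review_ceiling": cfg.tbil_review_ceiling,
                "venipuncture_verified": record.venipuncture_verified,
            },
        )
    )
    if review_fired:
        annotations.append(Annotation.REVIEW_SAMPLING.value)
        return finish(ReportStatus.VERIFY_PREANALYTICS)

    if annotations:
        return finish(ReportStatus.REPORT_WITH_ANNOTATION)
    return finish(ReportStatus.REPORT)


def decide_batch(
    records: Sequence[SampleRecord] | Iterable[SampleRecord],
    cfg: ThresholdConfig | None = None,
) -> list[ReportDecision]:
    """Element-wise :func:`decide` over a batch, preserving order.

    Raises on an empty batch; per-record failures are re-raised with the
    sample id attached.  A per-status summary is written to the log.
    """
    records = list(records)
    if not records:
        raise ValueError("empty batch: no samples to decide")
    decisions: list[ReportDecision] = []
    for record in records:
        try:
            decisions.append(decide(record, cfg))
        except ValueError as exc:
            raise ValueError(f"sample {record.sample_id!r}: {exc}") from exc
    counts = Counter(d.status.value for d in decisions)
    logger.info(
        "decided %d samples: %s",
        len(decisions),
        ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
    )
    return decisions
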