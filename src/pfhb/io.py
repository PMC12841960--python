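"""CSV / YAML / JSON interfaces.

All tabular files are UTF-8, comma-delimited CSV with a header row and dot
decimal separator; free hemoglobin is always mg/L and bilirubin always
umol/L in files (unit conversion is explicit, never inferred).  Validation
failures name the file, row (1-based data rows) and column.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .comparison import ComparisonResult
from .cutoff import CutoffResult
from .measurement import AbsorbanceTriplet, HILIndices
from .reporting import ReportDecision, SampleRecord, ThresholdConfig

__all__ = [
    "read_absorbances",
    "read_panel",
    "read_paired",
    "load_threshold_config",
    "write_decisions",
    "write_comparison_json",
    "write_cutoff_json",
    "comparison_to_dict",
]

PathLike = Union[str, Path]

ABSORBANCE_COLUMNS = ["sample_id", "a380", "a415", "a450"]
PANEL_NUMERIC = ["h_index", "i_index", "l_index"]
PANEL_OPTIONAL_NUMERIC = ["fhb_mg_l", "tbil_umol_l", "dbil_umol_l"]
PANEL_BOOLEAN = [
    "lipemia_present",
    "parenteral_nutrition",
    "nutrition_discontinuable",
    "propofol_sedation",
    "sedation_adjustable",
    "venipuncture_verified",
    "clinician_requested",
]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _read_csv(path: PathLike, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records (empty file)") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    return df


def _num(path: Path, row: int, col: str, raw: str, optional: bool = False) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        if optional:
            return None
        raise ValueError(f"{path}: row {row}, column {col!r}: missing value")
    try:
        return float(raw)
    except ValueError:
        raise ValueError(
            f"{path}: row {row}, column {col!r}: non-numeric value {raw!r}"
        ) from None


def _bool(path: Path, row: int, col: str, raw: str) -> bool:
    s = raw.strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(
        f"{path}: row {row}, column {col!r}: cannot parse boolean from {raw!r}"
    )


def read_absorbances(path: PathLike) -> list[tuple[str, AbsorbanceTriplet]]:
    """Read raw Harboe absorbance triplets."""
    path = Path(path)
    df = _read_csv(path, ABSORBANCE_COLUMNS)
    out = []
    for k, rec in enumerate(df.to_dict("records"), start=1):
        values = {c: _num(path, k, c, rec[c]) for c in ("a380", "a415", "a450")}
        try:
            triplet = AbsorbanceTriplet(**values)
        except ValueError as exc:
            raise ValueError(f"{path}: row {k}: {exc}") from None
        out.append((str(rec["sample_id"]), triplet))
    return out


def read_panel(path: PathLike) -> list[SampleRecord]:
    """Read per-sample measurement panels into :class:`SampleRecord` rows."""
    path = Path(path)
    df = _read_csv(path, ["sample_id"] + PANEL_NUMERIC + PANEL_BOOLEAN)
    records = []
    for k, rec in enumerate(df.to_dict("records"), start=1):
        numeric = {c: _num(path, k, c, rec[c]) for c in PANEL_NUMERIC}
        optional = {
            c: _num(path, k, c, rec.get(c, ""), optional=True)
            for c in PANEL_OPTIONAL_NUMERIC
        }
        flags = {c: _bool(path, k, c, rec[c]) for c in PANEL_BOOLEAN}
        try:
            records.append(
                SampleRecord(
                    sample_id=str(rec["sample_id"]),
                    hil=HILIndices(
                        h_index=numeric["h_index"],
                        i_index=numeric["i_index"],
                        l_index=numeric["l_index"],
                    ),
                    fhb=optional["fhb_mg_l"],
                    tbil=optional["tbil_umol_l"],
                    dbil=optional["dbil_umol_l"],
                    **flags,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {k}: {exc}") from None
    return records


def read_paired(
    path: PathLike,
    x_col: str = "fhb_mg_l",
    y_col: str = "efhb_mg_l",
    extra_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Read paired-measurement columns (plus any extras) as floats."""
    path = Path(path)
    cols = [x_col, y_col, *extra_cols]
    df = _read_csv(path, cols)
    out = {}
    for c in cols:
        vals = []
        for k, raw in enumerate(df[c], start=1):
            vals.append(_num(path, k, c, raw))
        out[c] = vals
    return pd.DataFrame(out)


def load_threshold_config(path: Optional[PathLike] = None) -> ThresholdConfig:
    """Load thresholds from a YAML mapping; absent keys take the defaults."""
    if path is None:
        return ThresholdConfig()
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping of threshold fields")
    valid = {f.name for f in dataclasses.fields(ThresholdConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"{path}: unknown threshold field(s) {sorted(unknown)}")
    return ThresholdConfig(**{k: float(v) for k, v in data.items()})


def write_decisions(decisions: list[ReportDecision], path: PathLike) -> None:
    """Write decisions as CSV with JSON-encoded rule traces."""
    rows = [
        {
            "sample_id": d.sample_id,
            "status": d.status.value,
            "annotations": ";".join(d.annotations),
            "rule_trace": json.dumps(
                [
                    {"rule_id": r.rule_id, "fired": r.fired, "inputs": dict(r.inputs)}
                    for r in d.rule_trace
                ]
            ),
        }
        for d in decisions
    ]
    pd.DataFrame(rows, columns=["sample_id", "status", "annotations", "rule_trace"]).to_csv(
        path, index=False
    )


def _ci(ci) -> Optional[dict]:
    if ci is None:
        return None
    return {"low": ci.low, "high": ci.high, "level": ci.level}


def comparison_to_dict(result: ComparisonResult) -> dict:
    pb, ba, sp = result.passing_bablok, result.bland_altman, result.spearman
    return {
        "n": result.n,
        "difference_direction": result.difference_direction,
        "passing_bablok": {
            "slope": pb.slope,
            "slope_ci": _ci(pb.slope_ci),
            "intercept": pb.intercept,
            "intercept_ci": _ci(pb.intercept_ci),
            "n_slopes": pb.n_slopes,
            "ci_level": pb.ci_level,
        },
        "bland_altman": {
            "bias": ba.bias,
            "bias_ci": _ci(ba.bias_ci),
            "loa_low": ba.loa_low,
            "loa_high": ba.loa_high,
            "sd": ba.sd,
            "loa_multiplier": ba.loa_multiplier,
        },
        "spearman": {
            "rho": sp.rho,
            "ci": _ci(sp.ci),
            "p_value": sp.p_value,
        },
    }


def write_comparison_json(result: ComparisonResult, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(comparison_to_dict(result), fh, indent=2)
        fh.write("\n")


def write_cutoff_json(result: CutoffResult, path: PathLike, with_trace: bool = True) -> None:
    payload = {
        "cutoff": result.cutoff,
        "analyte": result.analyte,
        "window": result.window,
        "rel_threshold": result.rel_threshold,
        "n_points": result.n_points,
    }
    if with_trace:
        payload["trace"] = [
            {"bilirubin": b, "rolling_median_rel_delta": m} for b, m in result.trace
        ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
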