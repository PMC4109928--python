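"""Survey CSV reading/writing with validation, and run configuration.

Column names carry explicit unit suffixes (``DIC_umol_L``,
``d13C_DIC_permil``, ...) because the fit mixes heterogeneous units in one
objective — a silent mmol/L survey would corrupt everything downstream.
Malformed files are rejected with per-row, per-column messages.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields

import pandas as pd
import yaml

from .degas import ModelParams
from .fit import FitConfig

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "SurveyValidationError",
    "read_survey",
    "write_survey",
    "validate_survey",
    "RunConfig",
]

REQUIRED_COLUMNS = (
    "site_id",
    "date",
    "temperature_C",
    "pH",
    "DIC_umol_L",
    "d13C_DIC_permil",
)
OPTIONAL_COLUMNS = ("discharge_L_s", "catchment_area_km2")

#: closed/open numeric ranges per column: (lo, hi, lo_open, hi_open)
_RANGES = {
    "temperature_C": (-2.0, 40.0, False, False),
    "pH": (2.0, 12.0, False, False),
    "DIC_umol_L": (0.0, 1e5, True, True),
    "d13C_DIC_permil": (-40.0, 5.0, False, False),
    "discharge_L_s": (0.0, math.inf, False, True),
    "catchment_area_km2": (0.0, math.inf, True, True),
}


class SurveyValidationError(ValueError):
    """Raised with a per-row error report when a survey fails validation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__(
            "survey validation failed:\n" + "\n".join(f"  {e}" for e in errors)
        )


def validate_survey(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, numeric parsing and physical ranges.

    Row numbers in messages are 1-based data rows (header excluded).
    Returns the table with numeric columns coerced to float.
    """
    errors: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SurveyValidationError([f"missing required column(s): {missing}"])

    table = table.copy()
    numeric = [c for c in _RANGES if c in table.columns]
    for col in numeric:
        parsed = pd.to_numeric(table[col], errors="coerce")
        for idx in table.index[parsed.isna() & table[col].notna()]:
            errors.append(f"row {idx + 1}: {col} {table.loc[idx, col]!r} is not numeric")
        for idx in table.index[parsed.isna() & table[col].isna()]:
            if col in REQUIRED_COLUMNS:
                errors.append(f"row {idx + 1}: {col} is missing")
        table[col] = parsed
        lo, hi, lo_open, hi_open = _RANGES[col]
        ok_lo = parsed > lo if lo_open else parsed >= lo
        ok_hi = parsed < hi if hi_open else parsed <= hi
        for idx in table.index[parsed.notna() & ~(ok_lo & ok_hi)]:
            errors.append(
                f"row {idx + 1}: {col} {float(parsed[idx])!r} outside "
                f"{'(' if lo_open else '['}{lo}, {hi}{')' if hi_open else ']'}"
            )
    for idx in table.index[table["site_id"].isna()]:
        errors.append(f"row {idx + 1}: site_id is missing")
    if errors:
        raise SurveyValidationError(errors)
    return table


def read_survey(path) -> pd.DataFrame:
    """Read and validate a survey CSV."""
    table = pd.read_csv(
        path, dtype={"site_id": str, "date": str}, float_precision="round_trip"
    )
    return validate_survey(table)


def write_survey(table: pd.DataFrame, path) -> None:
    """Write a survey table; full float precision so round-trips are lossless."""
    cols = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS) if c in table.columns]
    table.loc[:, cols].to_csv(path, index=False, float_format="%.17g")


@dataclass
class RunConfig:
    """Complete, serializable configuration of a model/fit run."""

    model: ModelParams = field(default_factory=ModelParams)
    fit: FitConfig = field(default_factory=FitConfig)
    gw_d13c: float = -25.0
    gw_d13c_bounds: tuple[float, float] | None = None
    sigma_dic: float = 50.0
    sigma_ph: float = 0.05
    sigma_d13c: float = 0.3
    seed: int = 0

    def to_dict(self) -> dict:
        doc = asdict(self)
        if doc["gw_d13c_bounds"] is not None:
            doc["gw_d13c_bounds"] = list(doc["gw_d13c_bounds"])
        doc["fit"]["gw_ph_bounds"] = list(doc["fit"]["gw_ph_bounds"])
        if doc["fit"]["gw_d13c_bounds"] is not None:
            doc["fit"]["gw_d13c_bounds"] = list(doc["fit"]["gw_d13c_bounds"])
        return doc

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        model = ModelParams(**doc.pop("model", {}))
        fit_doc = dict(doc.pop("fit", {}))
        for key in ("gw_ph_bounds", "gw_d13c_bounds"):
            if fit_doc.get(key) is not None:
                fit_doc[key] = tuple(fit_doc[key])
        fit = FitConfig(**fit_doc)
        if doc.get("gw_d13c_bounds") is not None:
            doc["gw_d13c_bounds"] = tuple(doc["gw_d13c_bounds"])
        known = {f.name for f in fields(cls)} - {"model", "fit"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(model=model, fit=fit, **doc)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})
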