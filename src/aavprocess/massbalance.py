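"""Upstream/downstream mass-balance arithmetic.

Titer-to-total conversion, full:total particle ratio, per-step recovery,
impurity clearance, compounded downstream recovery, platform equivalence
ratios and TFF volume reduction. Reporting follows the field's conventions:
integer percent for ratios and clearances, one decimal for fold
equivalences; the raw unrounded value is always retained alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "HarvestRecord",
    "UnitOperationRecord",
    "RecoveryResult",
    "ClearanceResult",
    "total_yield",
    "full_particle_ratio",
    "step_recovery",
    "clearance",
    "compound_recovery",
    "equivalence_ratio",
    "vrf_volumes",
    "read_records_csv",
    "write_records_csv",
    "build_report",
]


class HarvestRecord(BaseModel):
    """One crude-harvest measurement (titers by qPCR and ELISA)."""

    model_config = ConfigDict(extra="forbid")

    volume_mL: float = Field(gt=0)
    vg_per_mL: float = Field(default=0.0, ge=0)
    vp_per_mL: float | None = Field(default=None, ge=0)
    cells_lysed: float | None = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _subset(self) -> "HarvestRecord":
        # genome-containing particles are a subset of total particles
        if self.vp_per_mL is not None and self.vg_per_mL > self.vp_per_mL:
            raise ValueError("vg_per_mL must not exceed vp_per_mL")
        return self


class UnitOperationRecord(BaseModel):
    """In/out product and impurity quantities for one downstream step."""

    model_config = ConfigDict(extra="forbid")

    name: str
    product_in: float = Field(ge=0)
    product_out: float = Field(ge=0)
    impurities_in: dict[str, float] = Field(default_factory=dict)
    impurities_out: dict[str, float] = Field(default_factory=dict)
    volume_in_mL: float = Field(gt=0)
    volume_out_mL: float = Field(gt=0)

    @model_validator(mode="after")
    def _nonneg(self) -> "UnitOperationRecord":
        for d in (self.impurities_in, self.impurities_out):
            for key, val in d.items():
                if val < 0:
                    raise ValueError(f"impurity {key!r} must be >= 0")
        return self


@dataclass(frozen=True)
class RecoveryResult:
    percent: float
    rounded: int
    over_recovery: bool  # >100% is assay noise: flagged, not rejected


@dataclass(frozen=True)
class ClearanceResult:
    percent: float
    rounded: int
    negative: bool  # impurity increased across the step


def total_yield(titer_per_mL: float, volume_mL: float) -> float:
    """Total quantity from a per-mL titer and a harvest volume."""
    if titer_per_mL < 0 or volume_mL < 0:
        raise ValueError("titer and volume must be >= 0")
    return titer_per_mL * volume_mL


def full_particle_ratio(
    vg_total: float, vp_total: float, *, rounded: bool = False
) -> float:
    """Percent of capsids carrying a genome (vg/vp x 100).

    With ``rounded=True`` returns the nearest-integer reporting value.
    """
    if vp_total <= 0:
        raise ValueError("vp_total must be > 0")
    if vg_total < 0:
        raise ValueError("vg_total must be >= 0")
    if vg_total > vp_total:
        raise ValueError(
            "vg_total exceeds vp_total: genome-containing particles "
            "cannot outnumber total particles"
        )
    pct = 100.0 * vg_total / vp_total
    return float(round(pct)) if rounded else pct


def step_recovery(product_out: float, product_in: float) -> RecoveryResult:
    """Percent product recovered across one unit operation."""
    if product_in <= 0:
        raise ValueError("product_in must be > 0")
    if product_out < 0:
        raise ValueError("product_out must be >= 0")
    pct = 100.0 * product_out / product_in
    return RecoveryResult(
        percent=pct, rounded=round(pct), over_recovery=pct > 100.0
    )


def clearance(impurity_in: float, impurity_out: float) -> ClearanceResult:
    """Percent impurity reduction across one unit operation.

    An impurity increase yields a negative clearance with a flag (not an
    error): assay noise can produce apparent increases.
    """
    if impurity_in <= 0:
        raise ValueError("impurity_in must be > 0")
    if impurity_out < 0:
        raise ValueError("impurity_out must be >= 0")
    pct = 100.0 * (impurity_in - impurity_out) / impurity_in
    return ClearanceResult(percent=pct, rounded=round(pct), negative=pct < 0)


def compound_recovery(step_recoveries: Iterable[float]) -> float:
    """Product of per-step fractional recoveries (empty list -> 1.0)."""
    out = 1.0
    for r in step_recoveries:
        if not (0.0 <= r <= 1.5):
            raise ValueError(
                f"step recovery {r} outside the plausible range [0, 1.5]"
            )
        out *= r
    return out


def equivalence_ratio(
    quantity_a: float,
    quantity_b: float,
    rounding: int | Literal["integer"] | None = None,
) -> float:
    """a/b with optional reporting rounding (decimals, or nearest integer)."""
    if quantity_b <= 0:
        raise ValueError("quantity_b must be > 0")
    ratio = quantity_a / quantity_b
    if rounding is None:
        return ratio
    if rounding == "integer":
        return float(round(ratio))
    return round(ratio, int(rounding))


def vrf_volumes(volume_in_mL: float, vrf: float) -> float:
    """Retentate volume after a volumetric reduction factor ``vrf``."""
    if volume_in_mL <= 0:
        raise ValueError("volume_in_mL must be > 0")
    if vrf < 1:
        raise ValueError("vrf must be >= 1")
    return volume_in_mL / vrf


# ---------------------------------------------------------------------------
# unit-operation record I/O and reporting
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = [
    "name",
    "product_in",
    "product_out",
    "volume_in_mL",
    "volume_out_mL",
]


def write_records_csv(
    records: Sequence[UnitOperationRecord], path: str | Path
) -> Path:
    """One row per step; impurities become paired ``<name>_in/_out`` columns."""
    impurity_names = sorted(
        {k for r in records for k in (*r.impurities_in, *r.impurities_out)}
    )
    rows = []
    for r in records:
        row = {
            "name": r.name,
            "product_in": r.product_in,
            "product_out": r.product_out,
            "volume_in_mL": r.volume_in_mL,
            "volume_out_mL": r.volume_out_mL,
        }
        for imp in impurity_names:
            row[f"{imp}_in"] = r.impurities_in.get(imp, float("nan"))
            row[f"{imp}_out"] = r.impurities_out.get(imp, float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_records_csv(path: str | Path) -> list[UnitOperationRecord]:
    df = pd.read_csv(path)
    impurity_names = sorted(
        c[: -len("_in")]
        for c in df.columns
        if c.endswith("_in")
        and c not in _FIXED_COLUMNS
        and f"{c[:-3]}_out" in df.columns
    )
    records = []
    for _, row in df.iterrows():
        imps_in = {}
        imps_out = {}
        for imp in impurity_names:
            if not math.isnan(row[f"{imp}_in"]):
                imps_in[imp] = float(row[f"{imp}_in"])
            if not math.isnan(row[f"{imp}_out"]):
                imps_out[imp] = float(row[f"{imp}_out"])
        records.append(
            UnitOperationRecord(
                name=str(row["name"]),
                product_in=float(row["product_in"]),
                product_out=float(row["product_out"]),
                volume_in_mL=float(row["volume_in_mL"]),
                volume_out_mL=float(row["volume_out_mL"]),
                impurities_in=imps_in,
                impurities_out=imps_out,
            )
        )
    return records


def build_report(records: Sequence[UnitOperationRecord]) -> pd.DataFrame:
    """Recovery/clearance table, one row per step plus a compounded total."""
    rows = []
    fractions = []
    for r in records:
        rec = step_recovery(r.product_out, r.product_in)
        fractions.append(min(rec.percent / 100.0, 1.5))
        row: dict[str, object] = {
            "step": r.name,
            "recovery_pct": rec.percent,
            "recovery_pct_rounded": rec.rounded,
            "over_recovery": rec.over_recovery,
        }
        for imp, val_in in sorted(r.impurities_in.items()):
            if imp in r.impurities_out and val_in > 0:
                cl = clearance(val_in, r.impurities_out[imp])
                row[f"{imp}_clearance_pct"] = cl.percent
                row[f"{imp}_clearance_pct_rounded"] = cl.rounded
        rows.append(row)
    df = pd.DataFrame(rows)
    if rows:
        df.loc[len(df)] = {
            "step": "compounded",
            "recovery_pct": 100.0 * compound_recovery(fractions),
            "recovery_pct_rounded": round(100.0 * compound_recovery(fractions)),
            "over_recovery": False,
        }
    return df
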