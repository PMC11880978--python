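"""Combined AXIN1+AXIN2 pool composition per condition.

Converts the bridged AXIN1:AXIN2 ratio into the two pool fractions of the
untreated wild-type reference (set to 100% combined), then propagates
condition-specific fold changes of each analyte into per-condition pool
components and totals — the numbers behind the pie charts.

Rounding convention
-------------------
In ``table`` mode every fold change and percentage is rounded to one
decimal (half-up) *before* it is propagated, so each printed cell is the
product/sum of printed inputs (78.1 x 1.9 = 148.4, not 78.1 x 1.884).
``exact`` mode carries full precision and rounds only on export.  All
rounding is done in decimal arithmetic so that ties like 295.65 round up.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .bridging import RatioEstimate

__all__ = [
    "FoldChange",
    "PoolEntry",
    "ConditionSpec",
    "round1",
    "pool_fractions",
    "fold_vs_wt",
    "scaled_component",
    "build_pool_table",
    "export_pools",
]

ROUNDING_MODES = ("table", "exact")


def _dec(x: float) -> Decimal:
    # str() gives the shortest decimal repr, so one-decimal inputs stay exact
    return Decimal(str(float(x)))


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (0.05 -> 0.1)."""
    return float(_dec(x).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _check_mode(rounding: str) -> None:
    if rounding not in ROUNDING_MODES:
        raise ValueError(f"rounding mode must be one of {ROUNDING_MODES}, got {rounding!r}")


@dataclass(frozen=True)
class FoldChange:
    """Fold change of one analyte in one condition relative to untreated WT."""

    analyte: str
    condition: str
    value: float
    source_percents: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"fold change must be >= 0, got {self.value}")
        object.__setattr__(self, "source_percents", tuple(self.source_percents))


@dataclass(frozen=True)
class PoolEntry:
    """Pool components of one condition, as percent of the WT combined pool."""

    condition: str
    pct_axin1: float
    pct_axin2: float
    total: float
    fold_axin1_vs_wt: Optional[float] = None
    fold_axin2_vs_wt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pct_axin1 < 0 or self.pct_axin2 < 0:
            raise ValueError("pool components must be >= 0")


@dataclass(frozen=True)
class ConditionSpec:
    """One output row: a condition and how its components are sourced.

    ``reference`` rows take the ratio-derived base fractions directly
    (total exactly 100); a ``axin2_absent`` row is a knockout whose AXIN2
    component is structurally zero, so no AXIN2 fold is required — as
    opposed to a merely missing fold, which is an error.
    """

    name: str
    reference: bool = False
    axin2_absent: bool = False


def pool_fractions(ratio_a1_to_a2: float) -> tuple[float, float]:
    """Split the combined pool (=100%) by the AXIN1:AXIN2 amount ratio.

    Returns ``(pct_axin1, pct_axin2)`` with pct_axin2 = 100/(1+ratio) and
    pct_axin1 = 100*ratio/(1+ratio), each reported to one decimal.
    """
    if not ratio_a1_to_a2 > 0:
        raise ValueError(f"ratio must be > 0, got {ratio_a1_to_a2}")
    share = 100.0 / (1.0 + ratio_a1_to_a2)
    return round1(share * ratio_a1_to_a2), round1(share)


def fold_vs_wt(
    percent_levels: Sequence[float],
    wt_percent: float = 100.0,
    *,
    analyte: str = "",
    condition: str = "",
    rounding: str = "table",
) -> FoldChange:
    """Fold change = mean of per-replicate percent levels over the WT level.

    In ``table`` mode the value is rounded to one decimal before any
    propagation, so downstream products match printed arithmetic.
    """
    _check_mode(rounding)
    levels = [float(x) for x in percent_levels]
    if not levels:
        raise ValueError("at least one percent level is required")
    if not wt_percent > 0:
        raise ValueError(f"wt_percent must be > 0, got {wt_percent}")
    value = sum(levels) / len(levels) / wt_percent
    if rounding == "table":
        value = round1(value)
    return FoldChange(
        analyte=analyte,
        condition=condition,
        value=value,
        source_percents=tuple(levels),
    )


def scaled_component(base_pct: float, fold: FoldChange, *, rounding: str = "table") -> float:
    """One pool component: reference percentage times the fold change."""
    _check_mode(rounding)
    if base_pct < 0:
        raise ValueError("base percentage must be >= 0")
    if rounding == "table":
        return float(
            (_dec(base_pct) * _dec(fold.value)).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
    return base_pct * fold.value


def build_pool_table(
    ratio: Union[RatioEstimate, float],
    folds: Iterable[FoldChange],
    conditions: Sequence[ConditionSpec],
    *,
    rounding: str = "table",
) -> list[PoolEntry]:
    """Assemble the per-condition pool table from ratio and fold changes.

    The reference rows get the ratio-derived base fractions; every other
    row scales each base fraction by that condition's analyte fold change.
    A missing fold for a declared (non-knockout) condition is an error.
    Totals are componentwise sums of the (rounded, in table mode)
    components, so printed totals always equal the sum of printed parts.
    """
    _check_mode(rounding)
    ratio_value = ratio.mean if isinstance(ratio, RatioEstimate) else float(ratio)
    base_a1, base_a2 = pool_fractions(ratio_value)
    if rounding == "exact":
        share = 100.0 / (1.0 + ratio_value)
        base_a1, base_a2 = share * ratio_value, share

    by_key: dict[tuple[str, str], FoldChange] = {}
    for f in folds:
        by_key[(f.condition, f.analyte.upper())] = f

    entries: list[PoolEntry] = []
    for spec in conditions:
        if spec.reference:
            total = base_a1 + base_a2 if rounding == "exact" else float(
                _dec(base_a1) + _dec(base_a2)
            )
            entries.append(
                PoolEntry(
                    condition=spec.name,
                    pct_axin1=base_a1,
                    pct_axin2=base_a2,
                    total=total,
                )
            )
            continue
        f1 = by_key.get((spec.name, "AXIN1"))
        if f1 is None:
            raise ValueError(f"missing AXIN1 fold change for condition {spec.name!r}")
        if rounding == "table":
            f1 = FoldChange(f1.analyte, f1.condition, round1(f1.value), f1.source_percents)
        comp1 = scaled_component(base_a1, f1, rounding=rounding)
        if spec.axin2_absent:
            comp2 = 0.0
            f2 = None
        else:
            f2 = by_key.get((spec.name, "AXIN2"))
            if f2 is None:
                raise ValueError(
                    f"missing AXIN2 fold change for condition {spec.name!r} "
                    "(declare axin2_absent for knockouts)"
                )
            if rounding == "table":
                f2 = FoldChange(f2.analyte, f2.condition, round1(f2.value), f2.source_percents)
            comp2 = scaled_component(base_a2, f2, rounding=rounding)
        total = (
            comp1 + comp2 if rounding == "exact" else float(_dec(comp1) + _dec(comp2))
        )
        entries.append(
            PoolEntry(
                condition=spec.name,
                pct_axin1=comp1,
                pct_axin2=comp2,
                total=total,
                fold_axin1_vs_wt=f1.value,
                fold_axin2_vs_wt=None if f2 is None else f2.value,
            )
        )
    return entries


def export_pools(
    entries: Sequence[PoolEntry],
    csv_path: Union[str, Path, None] = None,
    json_path: Union[str, Path, None] = None,
) -> dict:
    """Write the pool table as CSV and/or pie-chart-ready JSON.

    Returns the JSON-serializable payload regardless of which paths are
    given, so callers can embed it in a run report.
    """
    if not entries:
        raise ValueError("no pool entries to export")
    payload = {
        "conditions": [
            {
                "condition": e.condition,
                "pct_axin1": e.pct_axin1,
                "pct_axin2": e.pct_axin2,
                "total": e.total,
                "fold_axin1_vs_wt": e.fold_axin1_vs_wt,
                "fold_axin2_vs_wt": e.fold_axin2_vs_wt,
                "pie": {"labels": ["AXIN1", "AXIN2"], "values": [e.pct_axin1, e.pct_axin2]},
            }
            for e in entries
        ]
    }
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["condition", "pct_axin1", "pct_axin2", "total",
                 "fold_axin1_vs_wt", "fold_axin2_vs_wt"]
            )
            for e in entries:
                w.writerow(
                    [e.condition, e.pct_axin1, e.pct_axin2, e.total,
                     "" if e.fold_axin1_vs_wt is None else e.fold_axin1_vs_wt,
                     "" if e.fold_axin2_vs_wt is None else e.fold_axin2_vs_wt]
                )
    if json_path is not None:
        Path(json_path).write_text(json.dumps(payload, indent=2))
    return payload
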