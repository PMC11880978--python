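"""CSV schemas, readers and validation diagnostics.

All tables are plain UTF-8 CSV with a header row and dot decimal
separators.  Readers return the domain objects of the analysis modules;
``validate_*`` functions return human-readable diagnostics (file, row,
message) instead of raising, so a run can report every schema problem at
once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .assays import DecaySeries, RecruitmentCount, ReporterMeasurement
from .bridging import BridgeExperiment, PairwiseComparison
from .quant_core import BandRecord

__all__ = [
    "Diagnostic",
    "BANDS_COLUMNS",
    "read_bands_csv",
    "read_bridge_design_csv",
    "assemble_bridge_experiments",
    "read_folds_csv",
    "read_reporter_csv",
    "read_chx_csv",
    "read_recruitment_csv",
    "validate_csv",
    "write_levels_csv",
    "write_ratio_json",
]

BANDS_COLUMNS = (
    "experiment_id", "blot_id", "lane", "condition", "analyte",
    "antibody", "dilution", "intensity", "loading_intensity",
)
BRIDGE_DESIGN_COLUMNS = ("experiment_id", "comparison", "antibody", "analyte_a", "analyte_b")
FOLDS_COLUMNS = ("condition", "analyte", "percents", "fold")
REPORTER_COLUMNS = ("replicate_id", "condition", "top_luc", "top_bgal", "fop_luc", "fop_bgal")
CHX_COLUMNS = ("condition", "time_h", "level_pct")
RECRUITMENT_COLUMNS = ("experiment_id", "setup", "n_recruited", "n_total")

_SCHEMAS = {
    "bands": BANDS_COLUMNS,
    "bridge_design": BRIDGE_DESIGN_COLUMNS,
    "folds": FOLDS_COLUMNS,
    "reporter": REPORTER_COLUMNS,
    "chx": CHX_COLUMNS,
    "recruitment": RECRUITMENT_COLUMNS,
}

_NUMERIC = {
    "bands": ("lane", "dilution", "intensity", "loading_intensity"),
    "folds": ("fold",),
    "reporter": ("top_luc", "top_bgal", "fop_luc", "fop_bgal"),
    "chx": ("time_h", "level_pct"),
    "recruitment": ("n_recruited", "n_total"),
    "bridge_design": (),
}


@dataclass(frozen=True)
class Diagnostic:
    path: str
    row: Optional[int]  # 1-based data row; None for file-level problems
    message: str

    def __str__(self) -> str:
        loc = f"{self.path}" if self.row is None else f"{self.path}:row {self.row}"
        return f"{loc}: {self.message}"


def _read(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def validate_csv(path: Union[str, Path], schema: str) -> list[Diagnostic]:
    """Check a CSV against one of the named schemas; return all problems."""
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    diags: list[Diagnostic] = []
    try:
        df = _read(path)
    except Exception as exc:  # unreadable / malformed file
        return [Diagnostic(str(path), None, f"cannot read CSV: {exc}")]
    required = set(_SCHEMAS[schema])
    optional = {"loading_intensity", "percents", "fold"}
    missing = (required - optional) - set(df.columns)
    for col in sorted(missing):
        diags.append(Diagnostic(str(path), None, f"missing column {col!r}"))
    if missing:
        return diags
    for col in _NUMERIC[schema]:
        if col not in df.columns:
            continue
        for i, raw in enumerate(df[col], start=1):
            if raw == "" and col in optional:
                continue
            try:
                float(raw)
            except ValueError:
                diags.append(
                    Diagnostic(str(path), i, f"non-numeric value {raw!r} in column {col!r}")
                )
    return diags


def _raise_on_diags(diags: list[Diagnostic]) -> None:
    if diags:
        raise ValueError("; ".join(str(d) for d in diags))


def read_bands_csv(path: Union[str, Path]) -> list[BandRecord]:
    _raise_on_diags(validate_csv(path, "bands"))
    df = _read(path)
    records = []
    for _, row in df.iterrows():
        loading = row.get("loading_intensity", "")
        records.append(
            BandRecord(
                experiment_id=row["experiment_id"],
                blot_id=row["blot_id"],
                lane=int(float(row["lane"])),
                condition=row["condition"],
                analyte=row["analyte"],
                antibody=row["antibody"],
                dilution=float(row["dilution"]),
                intensity=float(row["intensity"]),
                loading_intensity=None if loading == "" else float(loading),
            )
        )
    return records


def read_bridge_design_csv(path: Union[str, Path]) -> pd.DataFrame:
    _raise_on_diags(validate_csv(path, "bridge_design"))
    return _read(path)


def assemble_bridge_experiments(
    bands: list[BandRecord], design: pd.DataFrame
) -> list[BridgeExperiment]:
    """Join band records to the comparison design, one experiment at a time.

    The design has one row per (experiment, comparison index 1..3) naming
    the shared antibody and the two analytes; lanes are matched from the
    bands table by (experiment_id, antibody, analyte).
    """
    by_key: dict[tuple[str, str, str], list[BandRecord]] = {}
    for rec in bands:
        by_key.setdefault((rec.experiment_id, rec.antibody, rec.analyte), []).append(rec)

    experiments = []
    for exp_id, group in design.groupby("experiment_id", sort=False):
        comps: dict[int, PairwiseComparison] = {}
        for _, row in group.iterrows():
            idx = int(float(row["comparison"]))
            if idx not in (1, 2, 3):
                raise ValueError(f"comparison index must be 1..3, got {idx}")
            lanes_a = by_key.get((exp_id, row["antibody"], row["analyte_a"]), [])
            lanes_b = by_key.get((exp_id, row["antibody"], row["analyte_b"]), [])
            if not lanes_a or not lanes_b:
                raise ValueError(
                    f"no band records for comparison {idx} of experiment "
                    f"{exp_id!r} (antibody {row['antibody']!r})"
                )
            comps[idx] = PairwiseComparison(
                antibody=row["antibody"],
                analyte_a=row["analyte_a"],
                analyte_b=row["analyte_b"],
                lanes_a=tuple(lanes_a),
                lanes_b=tuple(lanes_b),
            )
        if set(comps) != {1, 2, 3}:
            raise ValueError(
                f"experiment {exp_id!r} needs comparisons 1, 2 and 3; "
                f"found {sorted(comps)}"
            )
        experiments.append(
            BridgeExperiment(
                experiment_id=str(exp_id), comp1=comps[1], comp2=comps[2], comp3=comps[3]
            )
        )
    return experiments


def read_folds_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Fold-change inputs: per (condition, analyte) either a semicolon-
    separated list of per-replicate percent levels or a precomputed fold."""
    _raise_on_diags(validate_csv(path, "folds"))
    df = _read(path)
    rows = []
    for i, row in df.iterrows():
        percents_raw = row.get("percents", "")
        percents = (
            [float(x) for x in percents_raw.split(";") if x.strip() != ""]
            if percents_raw
            else []
        )
        fold_raw = row.get("fold", "")
        fold = float(fold_raw) if fold_raw != "" else None
        if not percents and fold is None:
            raise ValueError(
                f"{path}:row {i + 1}: needs either percent levels or a fold"
            )
        rows.append(
            {
                "condition": row["condition"],
                "analyte": row["analyte"],
                "percents": percents,
                "fold": fold,
            }
        )
    return pd.DataFrame(rows)


def read_reporter_csv(path: Union[str, Path]) -> list[ReporterMeasurement]:
    _raise_on_diags(validate_csv(path, "reporter"))
    df = _read(path)
    return [
        ReporterMeasurement(
            replicate_id=row["replicate_id"],
            condition=row["condition"],
            top_luc=float(row["top_luc"]),
            top_bgal=float(row["top_bgal"]),
            fop_luc=float(row["fop_luc"]),
            fop_bgal=float(row["fop_bgal"]),
        )
        for _, row in df.iterrows()
    ]


def read_chx_csv(path: Union[str, Path]) -> list[DecaySeries]:
    _raise_on_diags(validate_csv(path, "chx"))
    df = _read(path)
    series = []
    for cond, group in df.groupby("condition", sort=False):
        pairs = sorted(
            (float(r["time_h"]), float(r["level_pct"])) for _, r in group.iterrows()
        )
        series.append(
            DecaySeries(
                condition=str(cond),
                timepoints=tuple(t for t, _ in pairs),
                levels=tuple(v for _, v in pairs),
            )
        )
    return series


def read_recruitment_csv(path: Union[str, Path]) -> list[RecruitmentCount]:
    _raise_on_diags(validate_csv(path, "recruitment"))
    df = _read(path)
    return [
        RecruitmentCount(
            experiment_id=row["experiment_id"],
            setup=row["setup"],
            n_recruited=int(float(row["n_recruited"])),
            n_total=int(float(row["n_total"])),
        )
        for _, row in df.iterrows()
    ]


def write_levels_csv(path: Union[str, Path], rows: list[dict]) -> None:
    pd.DataFrame(
        rows,
        columns=["condition", "analyte", "replicate_id", "normalized", "percent_of_reference"],
    ).to_csv(path, index=False)


def write_ratio_json(
    path: Union[str, Path],
    ratio,
    qc: Optional[dict] = None,
) -> None:
    payload = {
        "per_experiment": list(ratio.per_experiment),
        "mean": ratio.mean,
        "sem": ratio.sem,
        "n": ratio.n,
        "qc": qc or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2))
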