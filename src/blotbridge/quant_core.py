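"""Core data model and replicate statistics for densitometry quantification.

Band intensities arrive pre-quantified (2D densitometry of immunoblots).
This module normalizes them to a same-lane loading control (alpha-tubulin),
expresses conditions as percent of a reference condition per replicate, and
summarizes replicates as mean +/- SEM with two-tailed Student's t-tests.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as _st

__all__ = [
    "BandRecord",
    "NormalizedLevel",
    "RelativeLevel",
    "ReplicateSummary",
    "SignificanceCall",
    "normalize_to_loading",
    "relative_to_reference",
    "summarize",
    "student_t_test",
    "stars_for_p",
]


@dataclass(frozen=True)
class BandRecord:
    """One measured band on one blot lane.

    ``dilution`` is the fraction of undiluted lysate loaded in the lane
    (1.0 = undiluted, 0.1 = 1:10 diluted).  ``loading_intensity`` is the
    same-lane loading-control band (alpha-tubulin) and may be absent for
    bridging lanes, where all lanes share one lysate.
    """

    experiment_id: str
    blot_id: str
    lane: int
    condition: str
    analyte: str
    antibody: str
    dilution: float
    intensity: float
    loading_intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.lane < 1:
            raise ValueError(f"lane must be >= 1, got {self.lane}")
        if not (0.0 < self.dilution <= 1.0):
            raise ValueError(f"dilution must be in (0, 1], got {self.dilution}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")
        if self.loading_intensity is not None and not self.loading_intensity > 0:
            raise ValueError(
                f"loading_intensity must be > 0 when present "
                f"(blot {self.blot_id!r}, lane {self.lane})"
            )


@dataclass(frozen=True)
class NormalizedLevel:
    """Loading-control-normalized band intensity (dimensionless)."""

    condition: str
    analyte: str
    value: float
    replicate_id: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"normalized value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class RelativeLevel:
    """Normalized level expressed as percent of a reference condition."""

    condition: str
    analyte: str
    percent_of_reference: float
    replicate_id: str

    def __post_init__(self) -> None:
        if self.percent_of_reference < 0:
            raise ValueError("percent_of_reference must be >= 0")


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +/- SEM over independent replicates.

    SEM uses the sample standard deviation (n-1 denominator) divided by
    sqrt(n); a single replicate has SEM 0 by convention.
    """

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


#: Significance star thresholds: p < 0.001 -> ***, < 0.01 -> **, < 0.05 -> *.
_STAR_EDGES = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    for edge, label in _STAR_EDGES:
        if p < edge:
            return label
    return "ns"


@dataclass(frozen=True)
class SignificanceCall:
    p_value: float
    stars: str
    paired: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if self.stars != stars_for_p(self.p_value):
            raise ValueError(
                f"stars {self.stars!r} inconsistent with p={self.p_value}"
            )

    @classmethod
    def from_p(cls, p: float, paired: bool) -> "SignificanceCall":
        return cls(p_value=p, stars=stars_for_p(p), paired=paired)


def normalize_to_loading(record: BandRecord) -> NormalizedLevel:
    """Divide a band intensity by its same-lane loading-control intensity.

    Dilution is deliberately NOT applied here: dilution correction belongs
    to the bridging fits, which model intensity as slope x dilution.
    """
    if record.loading_intensity is None:
        raise ValueError(
            f"no loading-control intensity for blot {record.blot_id!r} "
            f"lane {record.lane} ({record.analyte})"
        )
    return NormalizedLevel(
        condition=record.condition,
        analyte=record.analyte,
        value=record.intensity / record.loading_intensity,
        replicate_id=record.experiment_id,
    )


def relative_to_reference(
    levels: Iterable[NormalizedLevel], reference_condition: str
) -> list[RelativeLevel]:
    """Express each level as percent of the reference condition.

    The reference is matched within each (replicate, analyte) group so that
    every independent experiment is scaled by its own reference lane; the
    reference condition itself maps to exactly 100.0.
    """
    groups: dict[tuple[str, str], list[NormalizedLevel]] = defaultdict(list)
    for lv in levels:
        groups[(lv.replicate_id, lv.analyte)].append(lv)

    out: list[RelativeLevel] = []
    for (replicate_id, analyte), group in groups.items():
        refs = [lv for lv in group if lv.condition == reference_condition]
        if not refs:
            raise ValueError(
                f"reference condition {reference_condition!r} missing in "
                f"replicate {replicate_id!r} for analyte {analyte!r}"
            )
        if len(refs) > 1:
            raise ValueError(
                f"reference condition {reference_condition!r} appears "
                f"{len(refs)} times in replicate {replicate_id!r} "
                f"for analyte {analyte!r}"
            )
        ref_value = refs[0].value
        if ref_value <= 0:
            raise ValueError(
                f"reference level is zero in replicate {replicate_id!r} "
                f"for analyte {analyte!r}"
            )
        for lv in group:
            pct = 100.0 if lv.condition == reference_condition else 100.0 * lv.value / ref_value
            out.append(
                RelativeLevel(
                    condition=lv.condition,
                    analyte=lv.analyte,
                    percent_of_reference=pct,
                    replicate_id=replicate_id,
                )
            )
    return out


def summarize(values: Sequence[float]) -> ReplicateSummary:
    """Mean and SEM (sample sd / sqrt(n)) of replicate values."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarize an empty collection")
    n = int(vals.size)
    mean = float(vals.mean())
    if n == 1 or np.all(vals == vals[0]):
        sem = 0.0  # identical replicates: exactly zero spread
    else:
        sem = float(vals.std(ddof=1) / math.sqrt(n))
    return ReplicateSummary(mean=mean, sem=sem, n=n)


def student_t_test(
    a: Sequence[float],
    b: Sequence[float],
    paired: bool,
    *,
    welch: bool = False,
) -> SignificanceCall:
    """Two-tailed Student's t-test between two replicate groups.

    The unpaired test pools variances (classical equal-variance Student's
    t); Welch's unequal-variance variant is available via ``welch=True``.
    Paired tests require equal lengths with matched replicate order.
    Degenerate inputs with zero variance and equal means (e.g. a paired
    test with all-zero differences) report p = 1.0 rather than NaN.
    """
    av = np.asarray(list(a), dtype=float)
    bv = np.asarray(list(b), dtype=float)
    if av.size < 2 or bv.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    if paired:
        if av.size != bv.size:
            raise ValueError(
                f"paired test requires equal lengths, got {av.size} and {bv.size}"
            )
        diffs = av - bv
        if np.all(diffs == 0):
            return SignificanceCall.from_p(1.0, paired=True)
        res = _st.ttest_rel(av, bv)
        p = float(res.pvalue)
    else:
        res = _st.ttest_ind(av, bv, equal_var=not welch)
        p = float(res.pvalue)
        if math.isnan(p):
            # zero pooled variance: identical constants -> no evidence;
            # distinct constants -> arbitrarily strong evidence
            p = 1.0 if av.mean() == bv.mean() else float(np.finfo(float).tiny)
    if math.isnan(p):
        p = 1.0
    p = min(max(p, float(np.finfo(float).tiny)), 1.0)
    return SignificanceCall.from_p(p, paired=paired)
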