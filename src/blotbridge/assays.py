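"""Auxiliary assay quantifications: TOP/FOP reporter, CHX decay, recruitment.

Three small models used alongside the densitometry pipeline:

* dual-luciferase TOP/FOP normalization — beta-catenin-dependent
  transcription as the ratio of beta-galactosidase-normalized TOP and FOP
  luciferase activities;
* cycloheximide-chase kinetics — first-order protein decay fitted on the
  log scale, yielding a rate constant and half-life;
* recruitment fractions — per-experiment percentages of cells showing
  co-localization, summarized with the experiment (not the cell) as the
  statistical unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .quant_core import ReplicateSummary, summarize

__all__ = [
    "ReporterMeasurement",
    "DecaySeries",
    "DecayFit",
    "RecruitmentCount",
    "top_fop_activity",
    "fit_first_order_decay",
    "recruitment_summary",
]


@dataclass(frozen=True)
class ReporterMeasurement:
    """One replicate of the dual reporter assay.

    TOP carries the beta-catenin-responsive promoter, FOP its mutated
    control; each well's luciferase signal is normalized by that well's
    constitutive beta-galactosidase signal to correct for transfection
    efficiency.
    """

    replicate_id: str
    condition: str
    top_luc: float
    top_bgal: float
    fop_luc: float
    fop_bgal: float

    def __post_init__(self) -> None:
        if self.top_luc < 0 or self.fop_luc < 0:
            raise ValueError("luciferase readouts must be >= 0")
        if not (self.top_bgal > 0 and self.fop_bgal > 0):
            raise ValueError("beta-galactosidase readouts must be > 0")


@dataclass(frozen=True)
class DecaySeries:
    """Loading-normalized protein levels (% of t=0) over a CHX time course."""

    condition: str
    timepoints: tuple[float, ...]
    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", tuple(float(t) for t in self.timepoints))
        object.__setattr__(self, "levels", tuple(float(v) for v in self.levels))
        if len(self.timepoints) != len(self.levels):
            raise ValueError("timepoints and levels differ in length")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be >= 0")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])) or len(
            set(self.timepoints)
        ) != len(self.timepoints):
            raise ValueError("timepoints must be strictly increasing")
        if 0.0 not in self.timepoints:
            raise ValueError("series must include t=0")
        if self.levels[self.timepoints.index(0.0)] != 100.0:
            raise ValueError("level at t=0 must be 100 (percent of t=0)")
        if any(v < 0 for v in self.levels):
            raise ValueError("levels must be >= 0")


@dataclass(frozen=True)
class DecayFit:
    """First-order decay fit: level(t) ~ N0 * exp(-k t)."""

    k: float
    half_life: Optional[float]
    n0: float
    decaying: bool

    def fraction_at(self, t: float) -> float:
        """Fraction of the t=0 level remaining at time t (h)."""
        return math.exp(-self.k * t)


@dataclass(frozen=True)
class RecruitmentCount:
    """Cells scored for co-localization in one experiment and setup."""

    experiment_id: str
    setup: str
    n_recruited: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not (0 <= self.n_recruited <= self.n_total):
            raise ValueError("n_recruited must be in [0, n_total]")


def top_fop_activity(m: ReporterMeasurement) -> float:
    """Normalized TOP/FOP ratio: (top_luc/top_bgal) / (fop_luc/fop_bgal).

    The FOP control is matched per replicate (same day, separate wells);
    a zero FOP luciferase signal leaves the ratio undefined.
    """
    if m.fop_luc == 0:
        raise ValueError(
            f"FOP luciferase is zero in replicate {m.replicate_id!r}; "
            "TOP/FOP ratio undefined"
        )
    return (m.top_luc / m.top_bgal) / (m.fop_luc / m.fop_bgal)


def fit_first_order_decay(series: DecaySeries) -> DecayFit:
    """Fit log(level) vs time by OLS with a free intercept.

    k is the negative slope (per hour); half-life is ln2/k for k > 0, and
    the series is flagged non-decaying (half-life None) otherwise.  Two or
    three timepoints cannot support more parameters than this, so the fit
    is deliberately log-linear rather than nonlinear least squares.
    """
    if any(v <= 0 for v in series.levels):
        raise ValueError(
            f"non-positive level in series {series.condition!r}; "
            "log-linear fit undefined"
        )
    if len(series.timepoints) < 2:
        raise ValueError("need at least 2 timepoints to fit a decay rate")
    t = np.asarray(series.timepoints)
    y = np.log(np.asarray(series.levels))
    slope, intercept = np.polyfit(t, y, 1)
    k = float(-slope)
    decaying = k > 0
    half_life = math.log(2.0) / k if decaying else None
    return DecayFit(k=k, half_life=half_life, n0=float(np.exp(intercept)), decaying=decaying)


def recruitment_summary(counts: Iterable[RecruitmentCount]) -> ReplicateSummary:
    """Mean +/- SEM of per-experiment recruitment percentages.

    Each experiment contributes a single percentage (100 * recruited /
    total); pooling cells across experiments would understate the
    between-experiment variance.
    """
    percentages = [100.0 * c.n_recruited / c.n_total for c in counts]
    if not percentages:
        raise ValueError("no recruitment counts supplied")
    return summarize(percentages)
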