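"""Chained three-antibody calibration of the endogenous AXIN1:AXIN2 ratio.

Two endogenous proteins detected by different antibodies cannot be compared
directly, because each antibody has its own unknown binding affinity.  The
bridge runs three same-antibody pairwise comparisons through GFP-tagged
fusion constructs:

    endo-AXIN1 vs GFP-AXIN1   (anti-AXIN1 antibody)
    GFP-AXIN1  vs GFP-AXIN2   (anti-GFP antibody)
    GFP-AXIN2  vs endo-AXIN2  (anti-AXIN2 antibody)

Within one comparison the shared antibody affinity cancels in the intensity
ratio, so the product of the three pairwise ratios equals the amount ratio
endo-AXIN1 : endo-AXIN2 with every affinity cancelled.

Each side of a comparison is loaded as a short dilution series (1:10, 1:2,
undiluted); a straight line through the origin is fitted to intensity vs
dilution and the pairwise ratio is the ratio of slopes.  Points that fall
below the linear response extrapolated from the lowest dilution are flagged
as detector-saturated and excluded from the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .quant_core import BandRecord, summarize

__all__ = [
    "PairwiseComparison",
    "BridgeExperiment",
    "RatioEstimate",
    "DilutionFit",
    "fit_dilution_response",
    "pairwise_ratio",
    "chained_ratio",
    "aggregate_ratio",
]


@dataclass(frozen=True)
class PairwiseComparison:
    """Two analytes detected side by side with one shared antibody."""

    antibody: str
    analyte_a: str
    analyte_b: str
    lanes_a: tuple[BandRecord, ...]
    lanes_b: tuple[BandRecord, ...]

    def __post_init__(self) -> None:
        if self.analyte_a == self.analyte_b:
            raise ValueError("a comparison needs two distinct analytes")
        object.__setattr__(self, "lanes_a", tuple(self.lanes_a))
        object.__setattr__(self, "lanes_b", tuple(self.lanes_b))
        if not self.lanes_a or not self.lanes_b:
            raise ValueError("each side needs at least one dilution point")
        for rec in (*self.lanes_a, *self.lanes_b):
            if rec.antibody != self.antibody:
                raise ValueError(
                    f"lane antibody {rec.antibody!r} differs from comparison "
                    f"antibody {self.antibody!r} (blot {rec.blot_id!r}, "
                    f"lane {rec.lane})"
                )


@dataclass(frozen=True)
class BridgeExperiment:
    """One replicate of the full three-comparison chain."""

    experiment_id: str
    comp1: PairwiseComparison  # endo-AXIN1 vs GFP-AXIN1 @ anti-AXIN1
    comp2: PairwiseComparison  # GFP-AXIN1 vs GFP-AXIN2 @ anti-GFP
    comp3: PairwiseComparison  # GFP-AXIN2 vs endo-AXIN2 @ anti-AXIN2

    def __post_init__(self) -> None:
        if self.comp1.analyte_b != self.comp2.analyte_a:
            raise ValueError(
                f"broken chain between comparison 1 and 2: "
                f"{self.comp1.analyte_b!r} != {self.comp2.analyte_a!r}"
            )
        if self.comp2.analyte_b != self.comp3.analyte_a:
            raise ValueError(
                f"broken chain between comparison 2 and 3: "
                f"{self.comp2.analyte_b!r} != {self.comp3.analyte_a!r}"
            )


@dataclass(frozen=True)
class RatioEstimate:
    """Per-experiment ratios with mean +/- SEM on the linear ratio scale."""

    per_experiment: tuple[float, ...]
    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_experiment", tuple(self.per_experiment))
        if any(r <= 0 for r in self.per_experiment):
            raise ValueError("ratio values must be strictly positive")


@dataclass(frozen=True)
class DilutionFit:
    """Least-squares line through the origin: intensity = slope x dilution."""

    slope: float
    used_points: int
    excluded_points: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if self.used_points < 1:
            raise ValueError("at least one point must be used")


def fit_dilution_response(
    points: Iterable[tuple[float, float]],
    saturation_tolerance: float = 0.20,
) -> DilutionFit:
    """Fit intensity = slope x dilution through the origin, dropping
    saturated points.

    The lowest-dilution (faintest) lane anchors the expected linear
    response, since low-signal lanes are least likely to saturate the
    detector.  Walking from the highest dilution downward, a point whose
    intensity falls below ``(1 - saturation_tolerance)`` times the anchored
    prediction is flagged as saturated and excluded; flagging stops at the
    first point consistent with linearity.  The anchor itself is always
    retained, and the slope is the through-origin least-squares estimate
    sum(d*I)/sum(d^2) over the retained points.
    """
    pts = sorted(((float(d), float(i)) for d, i in points), key=lambda p: p[0])
    if not pts:
        raise ValueError("no dilution points supplied")
    if all(i <= 0 for _, i in pts):
        raise ValueError("all intensities are zero; cannot fit a slope")
    d0, i0 = pts[0]
    anchor_slope = i0 / d0
    excluded = 0
    kept = list(pts)
    if anchor_slope > 0:
        for d, i in reversed(pts[1:]):  # highest dilution first
            if i < (1.0 - saturation_tolerance) * anchor_slope * d:
                kept.remove((d, i))
                excluded += 1
            else:
                break
    dil = np.array([d for d, _ in kept])
    inten = np.array([i for _, i in kept])
    slope = float(np.dot(dil, inten) / np.dot(dil, dil))
    if slope <= 0:
        raise ValueError("fitted slope is not positive")
    return DilutionFit(slope=slope, used_points=len(kept), excluded_points=excluded)


def _fit_side(lanes: Sequence[BandRecord], saturation_tolerance: float) -> DilutionFit:
    return fit_dilution_response(
        [(rec.dilution, rec.intensity) for rec in lanes],
        saturation_tolerance=saturation_tolerance,
    )


def pairwise_ratio(
    comp: PairwiseComparison, saturation_tolerance: float = 0.20
) -> float:
    """Amount ratio analyte_a : analyte_b from one same-antibody comparison.

    Both slopes carry the same antibody affinity factor, which cancels in
    the quotient, leaving the ratio of loaded amounts.
    """
    fit_a = _fit_side(comp.lanes_a, saturation_tolerance)
    fit_b = _fit_side(comp.lanes_b, saturation_tolerance)
    return fit_a.slope / fit_b.slope


def chained_ratio(
    exp: BridgeExperiment, saturation_tolerance: float = 0.20
) -> float:
    """endo-AXIN1 : endo-AXIN2 ratio for one bridge replicate.

    Product of the three pairwise ratios; each antibody's affinity and the
    (unknown) absolute amounts of the GFP fusion constructs cancel exactly.
    """
    r1 = pairwise_ratio(exp.comp1, saturation_tolerance)
    r2 = pairwise_ratio(exp.comp2, saturation_tolerance)
    r3 = pairwise_ratio(exp.comp3, saturation_tolerance)
    return r1 * r2 * r3


def aggregate_ratio(
    experiments: Iterable[BridgeExperiment],
    saturation_tolerance: float = 0.20,
    *,
    log_scale: bool = False,
) -> RatioEstimate:
    """Combine independent bridge replicates into mean +/- SEM.

    Ratios are averaged on the linear scale by default (the convention for
    reporting a ratio as mean +/- SEM over experiments); ``log_scale=True``
    averages log-ratios and back-transforms the mean (geometric mean), with
    the SEM then expressed on the log scale.
    """
    ratios = [chained_ratio(e, saturation_tolerance) for e in experiments]
    if not ratios:
        raise ValueError("no bridge experiments supplied")
    if log_scale:
        s = summarize([float(np.log(r)) for r in ratios])
        return RatioEstimate(
            per_experiment=tuple(ratios),
            mean=float(np.exp(s.mean)),
            sem=s.sem,
            n=s.n,
        )
    s = summarize(ratios)
    return RatioEstimate(per_experiment=tuple(ratios), mean=s.mean, sem=s.sem, n=s.n)
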