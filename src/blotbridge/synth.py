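"""Ground-truth generators for every input the pipeline consumes.

The measurement model for a band is

    intensity = min(cap, affinity x abundance x dilution x lane_load x exp(eps))

with ``eps ~ Normal(0, noise_sigma^2)`` (multiplicative log-normal error —
densitometry noise scales with signal and intensities stay positive) and a
per-lane loading factor ``lane_load ~ LogNormal(0, lane_loading_cv^2)``
shared by every band in the lane.  An optional detector saturation cap
clips bright bands.

Draw order is fixed so runs are reproducible given a seed: experiments in
order, lanes in output row order, and within a lane the loading factor
first, then the loading-control band's noise, then the target band's noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .assays import DecaySeries, RecruitmentCount, ReporterMeasurement
from .bridging import BridgeExperiment, PairwiseComparison
from .quant_core import BandRecord

__all__ = [
    "SyntheticTruth",
    "simulate_band",
    "simulate_bridge_study",
    "simulate_condition_panel",
    "simulate_chx",
    "simulate_reporter",
    "simulate_recruitment",
]

# canonical analyte / antibody names used by the bridge design
ENDO_AXIN1 = "AXIN1"
ENDO_AXIN2 = "AXIN2"
GFP_AXIN1 = "GFP-AXIN1"
GFP_AXIN2 = "GFP-AXIN2"
AB_AXIN1 = "anti-AXIN1"
AB_GFP = "anti-GFP"
AB_AXIN2 = "anti-AXIN2"
LOADING_ANALYTE = "alpha-tubulin"

RngLike = Union[np.random.Generator, int, None]


def _as_rng(rng: RngLike, fallback_seed: int = 0) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(fallback_seed if rng is None else rng)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a simulated study.

    ``abundances`` maps (condition, analyte) to a positive amount in
    arbitrary molar units; ``affinities`` maps antibody name to its
    detection efficiency (intensity units per amount).  Defaults mirror a
    plausible immunoblot: noise_sigma 0.15, lane_loading_cv 0.1, the
    1:10 / 1:2 / undiluted loading scheme, no saturation.
    """

    abundances: Mapping[tuple[str, str], float]
    affinities: Mapping[str, float]
    lane_loading_cv: float = 0.10
    noise_sigma: float = 0.15
    saturation_cap: Optional[float] = None
    dilutions: tuple[float, ...] = (0.1, 0.5, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "abundances", dict(self.abundances))
        object.__setattr__(self, "affinities", dict(self.affinities))
        object.__setattr__(self, "dilutions", tuple(self.dilutions))
        if any(v <= 0 for v in self.abundances.values()):
            raise ValueError("all abundances must be > 0")
        if any(v <= 0 for v in self.affinities.values()):
            raise ValueError("all affinities must be > 0")
        if self.lane_loading_cv < 0 or self.noise_sigma < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.saturation_cap is not None and self.saturation_cap <= 0:
            raise ValueError("saturation_cap must be > 0 when present")
        if any(not (0.0 < d <= 1.0) for d in self.dilutions):
            raise ValueError("dilutions must lie in (0, 1]")


def _band_intensity(
    truth: SyntheticTruth,
    abundance: float,
    affinity: float,
    dilution: float,
    lane_load: float,
    eps: float,
) -> float:
    raw = affinity * abundance * dilution * lane_load * np.exp(eps)
    if truth.saturation_cap is not None:
        raw = min(raw, truth.saturation_cap)
    return float(raw)


def simulate_band(
    truth: SyntheticTruth,
    condition: str,
    analyte: str,
    antibody: str,
    dilution: float,
    *,
    rng: RngLike = None,
    experiment_id: str = "exp1",
    blot_id: str = "blot1",
    lane: int = 1,
) -> BandRecord:
    """Draw one band record from the measurement model.

    With no generator supplied a fresh one is seeded from ``truth.seed``,
    so repeated calls with the same arguments are identical.
    """
    if (condition, analyte) not in truth.abundances:
        raise KeyError(f"unknown abundance key ({condition!r}, {analyte!r})")
    if antibody not in truth.affinities:
        raise KeyError(f"unknown antibody {antibody!r}")
    gen = _as_rng(rng, truth.seed)
    lane_load = float(np.exp(gen.normal(0.0, truth.lane_loading_cv)))
    eps = float(gen.normal(0.0, truth.noise_sigma))
    intensity = _band_intensity(
        truth,
        truth.abundances[(condition, analyte)],
        truth.affinities[antibody],
        dilution,
        lane_load,
        eps,
    )
    return BandRecord(
        experiment_id=experiment_id,
        blot_id=blot_id,
        lane=lane,
        condition=condition,
        analyte=analyte,
        antibody=antibody,
        dilution=dilution,
        intensity=intensity,
    )


def _dilution_lanes(
    truth: SyntheticTruth,
    gen: np.random.Generator,
    abundance: float,
    affinity: float,
    *,
    experiment_id: str,
    blot_id: str,
    condition: str,
    analyte: str,
    antibody: str,
    first_lane: int,
) -> tuple[BandRecord, ...]:
    lanes = []
    for j, d in enumerate(truth.dilutions):
        lane_load = float(np.exp(gen.normal(0.0, truth.lane_loading_cv)))
        eps = float(gen.normal(0.0, truth.noise_sigma))
        lanes.append(
            BandRecord(
                experiment_id=experiment_id,
                blot_id=blot_id,
                lane=first_lane + j,
                condition=condition,
                analyte=analyte,
                antibody=antibody,
                dilution=d,
                intensity=_band_intensity(truth, abundance, affinity, d, lane_load, eps),
            )
        )
    return tuple(lanes)


def simulate_bridge_study(
    true_ratio: float,
    n_experiments: int,
    truth: SyntheticTruth,
    *,
    rng: RngLike = None,
    condition: str = "SW480",
) -> list[BridgeExperiment]:
    """Simulate independent replicates of the three-comparison bridge.

    Endogenous AXIN1 abundance is ``true_ratio`` times the endogenous
    AXIN2 abundance; the GFP fusion construct amounts are drawn afresh for
    every experiment (they reflect transient transfection and cancel in
    the chained ratio).  Requires affinities for the three bridge
    antibodies in ``truth``.
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be > 0")
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    for ab in (AB_AXIN1, AB_GFP, AB_AXIN2):
        if ab not in truth.affinities:
            raise KeyError(f"truth lacks affinity for {ab!r}")
    gen = _as_rng(rng, truth.seed)
    endo_a2 = truth.abundances.get((condition, ENDO_AXIN2), 10.0)
    endo_a1 = true_ratio * endo_a2

    experiments = []
    for i in range(n_experiments):
        exp_id = f"exp{i + 1}"
        # transient expression varies a lot between transfections
        gfp_a1 = float(endo_a1 * np.exp(gen.normal(0.0, 0.5)))
        gfp_a2 = float(endo_a2 * np.exp(gen.normal(0.0, 0.5)))

        def comp(
            blot: str,
            antibody: str,
            analyte_a: str,
            ab_a: float,
            analyte_b: str,
            ab_b: float,
        ) -> PairwiseComparison:
            lanes_a = _dilution_lanes(
                truth, gen, ab_a, truth.affinities[antibody],
                experiment_id=exp_id, blot_id=blot, condition=condition,
                analyte=analyte_a, antibody=antibody, first_lane=1,
            )
            lanes_b = _dilution_lanes(
                truth, gen, ab_b, truth.affinities[antibody],
                experiment_id=exp_id, blot_id=blot, condition=condition,
                analyte=analyte_b, antibody=antibody,
                first_lane=1 + len(truth.dilutions),
            )
            return PairwiseComparison(
                antibody=antibody, analyte_a=analyte_a, analyte_b=analyte_b,
                lanes_a=lanes_a, lanes_b=lanes_b,
            )

        experiments.append(
            BridgeExperiment(
                experiment_id=exp_id,
                comp1=comp(f"{exp_id}-b1", AB_AXIN1, ENDO_AXIN1, endo_a1, GFP_AXIN1, gfp_a1),
                comp2=comp(f"{exp_id}-b2", AB_GFP, GFP_AXIN1, gfp_a1, GFP_AXIN2, gfp_a2),
                comp3=comp(f"{exp_id}-b3", AB_AXIN2, GFP_AXIN2, gfp_a2, ENDO_AXIN2, endo_a2),
            )
        )
    return experiments


def simulate_condition_panel(
    truth: SyntheticTruth,
    fold_map: Mapping[tuple[str, str], float],
    n_replicates: int,
    *,
    reference_condition: str = "WT",
    rng: RngLike = None,
) -> list[BandRecord]:
    """Simulate loading-control + target bands across conditions.

    ``fold_map`` maps (condition, analyte) to the true fold change of that
    analyte's abundance relative to ``reference_condition`` (which is
    emitted with fold 1 and need not appear in the map).  Every lane gets
    an alpha-tubulin loading band sharing the lane's loading factor, so
    loading-control normalization removes lane noise exactly at sigma=0.
    A fold of 0 encodes a knockout and produces a zero-intensity band.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if any(f < 0 for f in fold_map.values()):
        raise ValueError("folds must be >= 0")
    gen = _as_rng(rng, truth.seed)
    analytes = sorted({a for (_, a) in fold_map})
    conditions = [reference_condition] + sorted(
        {c for (c, _) in fold_map if c != reference_condition}
    )
    tubulin_affinity = truth.affinities.get(f"anti-{LOADING_ANALYTE}", 1.0)
    tubulin_abundance = 50.0

    records: list[BandRecord] = []
    for r in range(1, n_replicates + 1):
        exp_id = f"rep{r}"
        for analyte in analytes:
            affinity = truth.affinities.get(f"anti-{analyte}", 1.0)
            base = truth.abundances.get((reference_condition, analyte), 10.0)
            blot = f"{exp_id}-{analyte}"
            for lane, cond in enumerate(conditions, start=1):
                fold = 1.0 if cond == reference_condition else fold_map.get((cond, analyte), 1.0)
                lane_load = float(np.exp(gen.normal(0.0, truth.lane_loading_cv)))
                eps_load = float(gen.normal(0.0, truth.noise_sigma))
                eps_tgt = float(gen.normal(0.0, truth.noise_sigma))
                loading = _band_intensity(
                    truth, tubulin_abundance, tubulin_affinity, 1.0, lane_load, eps_load
                )
                target = (
                    0.0
                    if fold == 0
                    else _band_intensity(truth, base * fold, affinity, 1.0, lane_load, eps_tgt)
                )
                records.append(
                    BandRecord(
                        experiment_id=exp_id,
                        blot_id=blot,
                        lane=lane,
                        condition=cond,
                        analyte=analyte,
                        antibody=f"anti-{analyte}",
                        dilution=1.0,
                        intensity=target,
                        loading_intensity=loading,
                    )
                )
    return records


def simulate_chx(
    k_true: float,
    timepoints: Sequence[float],
    sigma: float = 0.0,
    rng: RngLike = None,
    *,
    condition: str = "WT",
) -> DecaySeries:
    """Simulate a cycloheximide chase: exponential decay, log-normal noise.

    Levels are re-expressed as percent of the (noisy) t=0 measurement, as
    a densitometry time course would be, so the series always starts at
    exactly 100.
    """
    if k_true < 0:
        raise ValueError("k_true must be >= 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    t = [float(x) for x in timepoints]
    if 0.0 not in t:
        raise ValueError("timepoints must include 0")
    gen = _as_rng(rng)
    raw = [np.exp(-k_true * ti) * np.exp(gen.normal(0.0, sigma)) for ti in t]
    base = raw[t.index(0.0)]
    levels = [100.0 * v / base for v in raw]
    levels[t.index(0.0)] = 100.0
    return DecaySeries(condition=condition, timepoints=tuple(t), levels=tuple(levels))


def simulate_reporter(
    activities: Mapping[str, float],
    n_replicates: int,
    sigma: float = 0.0,
    rng: RngLike = None,
    *,
    transfection_cv: float = 0.2,
    base_rate: float = 50.0,
) -> list[ReporterMeasurement]:
    """Simulate dual-reporter readouts with known TOP/FOP activities.

    ``activities`` maps condition to the true normalized TOP/FOP ratio.
    Transfection efficiency varies per well (log-normal beta-gal), and the
    luciferase signal carries multiplicative noise ``sigma``; at sigma=0
    the computed activity equals the truth exactly because beta-gal
    normalization removes the transfection variation.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if any(a < 0 for a in activities.values()):
        raise ValueError("activities must be >= 0")
    if sigma < 0 or transfection_cv < 0:
        raise ValueError("noise parameters must be >= 0")
    gen = _as_rng(rng)
    out = []
    for r in range(1, n_replicates + 1):
        rid = f"rep{r}"
        for cond in sorted(activities):
            act = activities[cond]
            top_bgal = float(np.exp(gen.normal(0.0, transfection_cv)))
            fop_bgal = float(np.exp(gen.normal(0.0, transfection_cv)))
            top_luc = float(act * base_rate * top_bgal * np.exp(gen.normal(0.0, sigma)))
            fop_luc = float(base_rate * fop_bgal * np.exp(gen.normal(0.0, sigma)))
            out.append(
                ReporterMeasurement(
                    replicate_id=rid, condition=cond,
                    top_luc=top_luc, top_bgal=top_bgal,
                    fop_luc=fop_luc, fop_bgal=fop_bgal,
                )
            )
    return out


def simulate_recruitment(
    p_true: float,
    n_cells: int,
    n_experiments: int,
    rng: RngLike = None,
    *,
    setup: str = "setup",
) -> list[RecruitmentCount]:
    """Draw per-experiment recruitment counts from Binomial(n_cells, p)."""
    if not (0.0 <= p_true <= 1.0):
        raise ValueError("p_true must be in [0, 1]")
    if n_cells < 1 or n_experiments < 1:
        raise ValueError("n_cells and n_experiments must be >= 1")
    gen = _as_rng(rng)
    return [
        RecruitmentCount(
            experiment_id=f"exp{i + 1}",
            setup=setup,
            n_recruited=int(gen.binomial(n_cells, p_true)),
            n_total=n_cells,
        )
        for i in range(n_experiments)
    ]
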