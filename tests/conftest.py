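"""Shared fixtures: the published pool-composition inputs and a noise-free
synthetic ground truth."""

from __future__ import annotations

import pytest

import blotbridge as bb

# Per-condition percent levels (vs untreated parental WT = 100) feeding the
# pool table, with the expected one-decimal components and totals.
FOLD_PERCENTS: dict[tuple[str, str], list[float]] = {
    ("AXIN2-/-", "AXIN1"): [161.9, 214.9],
    ("siAXIN2", "AXIN2"): [28.7],
    ("siAXIN2", "AXIN1"): [163.2],
    ("+/+ #1 G007-LK", "AXIN2"): [615.4],
    ("+/+ #1 G007-LK", "AXIN1"): [194.2],
    ("+/+ #2 ut", "AXIN2"): [141.2],
    ("+/+ #2 ut", "AXIN1"): [67.9],
    ("+/+ #2 G007-LK", "AXIN2"): [1353.8],
    ("+/+ #2 G007-LK", "AXIN1"): [179.9],
    ("AXIN2-/- #1 ut", "AXIN1"): [175.7],
    ("AXIN2-/- #1 G007-LK", "AXIN1"): [198.3],
    ("AXIN2-/- #2 ut", "AXIN1"): [226.9],
    ("AXIN2-/- #2 G007-LK", "AXIN1"): [218.4],
}

KNOCKOUTS = {
    "AXIN2-/-",
    "AXIN2-/- #1 ut",
    "AXIN2-/- #1 G007-LK",
    "AXIN2-/- #2 ut",
    "AXIN2-/- #2 G007-LK",
}

CONDITION_ORDER = [
    "SW480",
    "AXIN2-/-",
    "siAXIN2",
    "+/+ #1 ut",
    "+/+ #1 G007-LK",
    "+/+ #2 ut",
    "+/+ #2 G007-LK",
    "AXIN2-/- #1 ut",
    "AXIN2-/- #1 G007-LK",
    "AXIN2-/- #2 ut",
    "AXIN2-/- #2 G007-LK",
]
REFERENCES = {"SW480", "+/+ #1 ut"}

# condition -> (pct_axin1, pct_axin2, total)
EXPECTED_POOLS: dict[str, tuple[float, float, float]] = {
    "SW480": (78.1, 21.9, 100.0),
    "AXIN2-/-": (148.4, 0.0, 148.4),
    "siAXIN2": (125.0, 6.6, 131.6),
    "+/+ #1 ut": (78.1, 21.9, 100.0),
    "+/+ #1 G007-LK": (148.4, 135.8, 284.2),
    "+/+ #2 ut": (54.7, 30.7, 85.4),
    "+/+ #2 G007-LK": (140.6, 295.7, 436.3),
    "AXIN2-/- #1 ut": (140.6, 0.0, 140.6),
    "AXIN2-/- #1 G007-LK": (156.2, 0.0, 156.2),
    "AXIN2-/- #2 ut": (179.6, 0.0, 179.6),
    "AXIN2-/- #2 G007-LK": (171.8, 0.0, 171.8),
}

# condition -> (fold_axin1, fold_axin2 or None)
EXPECTED_FOLDS: dict[str, tuple[float, float | None]] = {
    "AXIN2-/-": (1.9, None),
    "siAXIN2": (1.6, 0.3),
    "+/+ #1 G007-LK": (1.9, 6.2),
    "+/+ #2 ut": (0.7, 1.4),
    "+/+ #2 G007-LK": (1.8, 13.5),
    "AXIN2-/- #1 ut": (1.8, None),
    "AXIN2-/- #1 G007-LK": (2.0, None),
    "AXIN2-/- #2 ut": (2.3, None),
    "AXIN2-/- #2 G007-LK": (2.2, None),
}

WT_RATIO = 3.56


@pytest.fixture(scope="session")
def table_folds() -> list[bb.FoldChange]:
    return [
        bb.fold_vs_wt(percents, analyte=analyte, condition=condition)
        for (condition, analyte), percents in FOLD_PERCENTS.items()
    ]


@pytest.fixture(scope="session")
def table_conditions() -> list[bb.ConditionSpec]:
    return [
        bb.ConditionSpec(
            name=name,
            reference=name in REFERENCES,
            axin2_absent=name in KNOCKOUTS,
        )
        for name in CONDITION_ORDER
    ]


@pytest.fixture
def noise_free_truth() -> bb.SyntheticTruth:
    return bb.SyntheticTruth(
        abundances={("SW480", "AXIN2"): 10.0},
        affinities={"anti-AXIN1": 5.0, "anti-GFP": 0.2, "anti-AXIN2": 11.0},
        lane_loading_cv=0.0,
        noise_sigma=0.0,
        seed=7,
    )
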