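"""Synthetic calibration curves and collections with known ground truth."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .calibration import CalibrationCurve, GeochronDate
from .chronology_builder import SampleAge
from .units import AnalysisUnit, CollectionUnit

__all__ = [
    "SyntheticTruth",
    "ScenarioFixture",
    "make_curve",
    "simulate_collection",
    "scenario_fixtures",
]


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated collection.

    ``boundaries[unit_id] = (older, younger)`` in cal BP; ``events`` and
    ``lab_sigmas`` are per-unit lists aligned with the generated dates.
    """

    boundaries: Dict[str, Tuple[float, float]]
    events: Dict[str, List[float]]
    lab_sigmas: Dict[str, List[float]]
    scenario_tags: List[str] = field(default_factory=list)
    seed: Optional[int] = None


def make_curve(
    kind: str = "identity",
    age_min: int = 0,
    age_max: int = 10_000,
    resolution: int = 1,
    slope: float = 1.0,
    intercept: float = 0.0,
    wiggle_amplitude: float = 50.0,
    wiggle_period: float = 500.0,
    curve_sigma: Union[float, str] = 0.0,
) -> CalibrationCurve:
    """Build a synthetic curve with a known functional form.

    kinds: ``identity`` (mu = theta), ``linear`` (mu = intercept + slope*theta,
    slope > 0), ``wiggly`` (linear plus a bounded sinusoid).  ``curve_sigma``
    is a constant, or ``"proportional"`` for 1% of age (floor 1 yr).
    """
    if not (0 <= age_min < age_max <= 55_000):
        raise ValueError("age range must lie within [0, 55000]")
    grid = np.arange(age_min, age_max + 1, resolution)
    theta = grid.astype(float)
    if kind == "identity":
        mu = theta.copy()
    elif kind == "linear":
        if slope <= 0:
            raise ValueError("linear curve requires slope > 0")
        mu = intercept + slope * theta
    elif kind == "wiggly":
        if slope <= 0:
            raise ValueError("wiggly curve requires a positive underlying slope")
        mu = intercept + slope * theta + wiggle_amplitude * np.sin(2 * np.pi * theta / wiggle_period)
    else:
        raise ValueError(f"unknown curve kind {kind!r}")
    if curve_sigma == "proportional":
        sigma = np.maximum(0.01 * theta, 1.0)
    else:
        sigma = np.full_like(theta, float(curve_sigma))
    return CalibrationCurve(grid=grid, mu=mu, sigma=sigma, name=f"synthetic-{kind}")


def simulate_collection(
    n_units: int,
    dates_per_unit: Union[int, Sequence[int]],
    curve: CalibrationCurve,
    seed: int,
    ordered: bool = False,
    age_range: Optional[Tuple[float, float]] = None,
    span_range: Tuple[float, float] = (200.0, 2_000.0),
    lab_sigma_range: Tuple[float, float] = (30.0, 150.0),
    collection_id: str = "sim",
) -> Tuple[CollectionUnit, SyntheticTruth]:
    """Simulate a collection unit with known boundaries, events and dates.

    Phase boundaries are drawn inside ``age_range`` (default: the central 80%
    of the curve); events are uniform within their phase; each observed 14C
    age is ``mu(true age) + N(0, lab sigma)`` with lab sigma log-uniform in
    ``lab_sigma_range``.  Units with zero requested dates become undated
    units placed by their depth.  Deterministic given ``seed``.
    """
    if n_units < 1:
        raise ValueError("need at least one unit")
    if isinstance(dates_per_unit, int):
        counts = [dates_per_unit] * n_units
    else:
        counts = list(dates_per_unit)
        if len(counts) != n_units:
            raise ValueError("dates_per_unit length must equal n_units")
    rng = np.random.default_rng(seed)

    lo = float(curve.grid[0])
    hi = float(curve.grid[-1])
    if age_range is None:
        pad = 0.1 * (hi - lo)
        age_range = (lo + pad, hi - pad)
    if age_range[0] >= age_range[1]:
        raise ValueError("infeasible age range")

    # draw disjoint phase windows oldest-first when ordered, free otherwise
    spans = rng.uniform(span_range[0], span_range[1], size=n_units)
    if ordered:
        total_span = spans.sum()
        free = (age_range[1] - age_range[0]) - total_span
        if free <= 0:
            raise ValueError("spans exceed the available age range")
        gaps = rng.dirichlet(np.ones(n_units + 1)) * free
        olders = np.empty(n_units)
        youngers = np.empty(n_units)
        top = age_range[1]  # oldest edge
        for k in range(n_units):
            top -= gaps[k]
            olders[k] = top
            youngers[k] = top - spans[k]
            top = youngers[k]
    else:
        centers = rng.uniform(age_range[0], age_range[1], size=n_units)
        olders = np.minimum(centers + spans / 2, hi - 1)
        youngers = np.maximum(centers - spans / 2, lo + 1)

    units: List[AnalysisUnit] = []
    boundaries: Dict[str, Tuple[float, float]] = {}
    events: Dict[str, List[float]] = {}
    lab_sigmas: Dict[str, List[float]] = {}
    tags: List[str] = []
    n_dated_so_far = 0
    for k in range(n_units):
        uid = f"{collection_id}-au{k + 1}"
        # depths would assert a stratigraphic order, so only ordered
        # collections get them (unit 0 deepest/oldest)
        depth = float(n_units - k) if ordered else None
        boundaries[uid] = (float(olders[k]), float(youngers[k]))
        events[uid] = []
        lab_sigmas[uid] = []
        dates: List[GeochronDate] = []
        for _ in range(counts[k]):
            true_age = rng.uniform(youngers[k], olders[k])
            sig = float(np.exp(rng.uniform(np.log(lab_sigma_range[0]), np.log(lab_sigma_range[1]))))
            obs = float(np.interp(true_age, curve.grid, curve.mu) + rng.normal(0.0, sig))
            events[uid].append(float(true_age))
            lab_sigmas[uid].append(sig)
            dates.append(
                GeochronDate.symmetric(
                    age=round(obs), error=round(sig), kind="radiocarbon",
                    lab_id=f"SIM-{collection_id}-{k + 1}-{len(dates) + 1}",
                )
            )
        if counts[k] == 0:
            dated_before = any(c > 0 for c in counts[:k])
            dated_after = any(c > 0 for c in counts[k + 1 :])
            if not ordered:
                tags.append("rule_e")  # no depths -> no stratigraphic relationship
            elif dated_before and dated_after:
                tags.append("rule_b")
            elif dated_before:  # only deeper units dated -> this one is above all
                tags.append("rule_c")
            elif dated_after:
                tags.append("rule_d")
            else:
                tags.append("rule_e")
        else:
            n_dated_so_far += 1
        units.append(AnalysisUnit(id=uid, name=f"layer {k + 1}", depth=depth, dates=dates))

    cu = CollectionUnit(id=collection_id, site_ref=f"site-{collection_id}", analysis_units=units)
    truth = SyntheticTruth(
        boundaries=boundaries, events=events, lab_sigmas=lab_sigmas,
        scenario_tags=tags, seed=seed,
    )
    return cu, truth


@dataclass
class ScenarioFixture:
    """A deterministic stratigraphic-inference scenario with known answers."""

    name: str
    cu: CollectionUnit
    dated_sample_ages: List[SampleAge]
    expected: List[SampleAge]
    external_constraints: Dict[str, Dict[str, int]] = field(default_factory=dict)


def _dated_unit(uid: str, depth: float) -> AnalysisUnit:
    return AnalysisUnit(
        id=uid, depth=depth,
        dates=[GeochronDate.symmetric(5000, 50, lab_id=f"FIX-{uid}")],
    )


def _sa(uid: str, older: Optional[int], younger: Optional[int], rule: str = "direct") -> SampleAge:
    return SampleAge(
        analysis_unit_ref=uid, chronology_kind="bounds", age=None,
        agelimitolder=older, agelimityounger=younger, provenance=rule,
    )


def scenario_fixtures() -> List[ScenarioFixture]:
    """One hand-built fixture per inference rule (a, b, b1, c, d, e).

    The dated sample ages are supplied directly so the rules are exercised in
    isolation from the MCMC stage; expected ranges are hand-computed.
    """
    fixtures: List[ScenarioFixture] = []

    # rule a: undated specimen drawn from a dated stratum
    cu = CollectionUnit(id="fix-a", analysis_units=[
        _dated_unit("D1", 1.0),
        AnalysisUnit(id="U1", subset_of="D1"),
    ])
    fixtures.append(ScenarioFixture(
        name="rule_a", cu=cu,
        dated_sample_ages=[_sa("D1", 12_000, 9_000)],
        expected=[_sa("U1", 12_000, 9_000, "rule_a")],
    ))

    # rule b: sandwiched between non-overlapping dated units
    cu = CollectionUnit(id="fix-b", analysis_units=[
        _dated_unit("D1", 3.0),
        AnalysisUnit(id="U1", depth=2.0),
        _dated_unit("D2", 1.0),
    ])
    fixtures.append(ScenarioFixture(
        name="rule_b", cu=cu,
        dated_sample_ages=[_sa("D1", 15_000, 13_000), _sa("D2", 11_000, 10_000)],
        expected=[_sa("U1", 13_000, 11_000, "rule_b")],
    ))

    # rule b1: sandwiched between overlapping dated units (time-averaging)
    cu = CollectionUnit(id="fix-b1", analysis_units=[
        _dated_unit("D1", 3.0),
        AnalysisUnit(id="U1", depth=2.0),
        _dated_unit("D2", 1.0),
    ])
    fixtures.append(ScenarioFixture(
        name="rule_b1", cu=cu,
        dated_sample_ages=[_sa("D1", 15_000, 12_000), _sa("D2", 13_000, 10_000)],
        expected=[_sa("U1", 15_000, 10_000, "rule_b1")],
    ))

    # rule c: above all dated units, reaching the surface
    cu = CollectionUnit(id="fix-c", analysis_units=[
        _dated_unit("D1", 2.0),
        AnalysisUnit(id="U1", depth=1.0),
    ])
    fixtures.append(ScenarioFixture(
        name="rule_c", cu=cu,
        dated_sample_ages=[_sa("D1", 9_000, 7_000)],
        expected=[_sa("U1", 7_000, 0, "rule_c")],
    ))

    # rule d: below all dated units, with an external older constraint
    cu = CollectionUnit(id="fix-d", analysis_units=[
        AnalysisUnit(id="U1", depth=2.0),
        _dated_unit("D1", 1.0),
    ])
    fixtures.append(ScenarioFixture(
        name="rule_d", cu=cu,
        dated_sample_ages=[_sa("D1", 9_000, 7_000)],
        expected=[_sa("U1", 14_000, 9_000, "rule_d")],
        external_constraints={"U1": {"older": 14_000}},
    ))

    # rule e: no stratigraphic relationship at all
    cu = CollectionUnit(id="fix-e", analysis_units=[
        _dated_unit("D1", 2.0),
        _dated_unit("D2", 1.0),
        AnalysisUnit(id="U1"),  # no depth, no order
    ])
    fixtures.append(ScenarioFixture(
        name="rule_e", cu=cu,
        dated_sample_ages=[_sa("D1", 16_000, 13_000), _sa("D2", 9_000, 6_000)],
        expected=[_sa("U1", 16_000, 6_000, "rule_e")],
    ))

    return fixtures
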