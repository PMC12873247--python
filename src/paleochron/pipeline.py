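"""End-to-end chronology construction for one collection unit."""

from __future__ import annotations

import copy
from typing import Dict, List, Optional, Tuple, Union

from .calibration import CalibrationCurve, calendar_density, calibrate_radiocarbon, summarize_control
from .chronology_builder import (
    Chronology,
    SampleAge,
    bounds_sample_ages,
    collection_age_bounds,
    event_sample_ages,
)
from .neotoma_io import filter_geochron_dates, select_collection
from .phase_model import PosteriorSamples, build_collection_model, sample_posterior
from .strat_inference import infer_all_undated
from .units import CollectionUnit

__all__ = ["apply_date_filters", "build_collection_chronologies"]


def apply_date_filters(cu: CollectionUnit, scan_keywords: bool = False) -> CollectionUnit:
    """Return a copy of the collection keeping only usable dates."""
    filtered = copy.deepcopy(cu)
    for au in filtered.analysis_units:
        usable, _ = filter_geochron_dates(au.dates, scan_keywords=scan_keywords)
        au.dates = usable
    return filtered


def build_collection_chronologies(
    cu: CollectionUnit,
    curve: CalibrationCurve,
    seed: int = 0,
    n_iter: int = 25_000,
    burn_in: int = 5_000,
    thin: int = 5,
    chains: int = 2,
    span_prior_exponent: Union[str, float] = "auto",
    overall_span_exponent: float = 0.0,
    external_constraints: Optional[Dict[str, Dict[str, int]]] = None,
    enforce_selection: bool = True,
) -> Tuple[Chronology, Chronology, PosteriorSamples]:
    """Build the bounds and event chronologies for one collection unit.

    Filters the dates, fits the phase model, extracts both chronology types,
    infers undated-unit ranges per chronology, and assembles collection-level
    age bounds over all units.  Returns ``(bounds, event, samples)``.
    """
    filtered = apply_date_filters(cu)
    if enforce_selection and not select_collection(filtered):
        raise ValueError(
            f"collection {cu.id} is ineligible: no usable radiocarbon date with "
            "(age - error) < 30,000 14C BP"
        )
    model = build_collection_model(filtered, curve)
    samples = sample_posterior(
        model,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=thin,
        chains=chains,
        seed=seed,
        span_prior_exponent=span_prior_exponent,
        overall_span_exponent=overall_span_exponent,
    )

    controls = []
    for au in filtered.analysis_units:
        for d in au.dates:
            dens = calibrate_radiocarbon(d, curve) if d.kind == "radiocarbon" else calendar_density(d, curve)
            ctrl = summarize_control(dens, d)
            ctrl.analysis_unit_ref = au.id
            controls.append(ctrl)

    chronologies: List[Chronology] = []
    for kind, dated_rows in (
        ("bounds", bounds_sample_ages(samples)),
        ("event", event_sample_ages(samples)),
    ):
        inferred = infer_all_undated(filtered, dated_rows, external_constraints=external_constraints)
        rows = dated_rows + inferred
        older, younger = collection_age_bounds(rows)
        chronologies.append(
            Chronology(
                collectionunit_ref=cu.id,
                kind=kind,
                ageboundolder=older,
                ageboundyounger=younger,
                sample_ages=rows,
                controls=controls,
            )
        )
    bounds, event = chronologies
    return bounds, event, samples
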