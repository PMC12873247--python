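"""Turn posterior samples into 'event' and 'bounds' chronologies.

The event chronology summarizes the predictive ("new event") age draws of
each dated unit at the 0.3173 / 0.5 / 0.6827 from-old quantiles; the bounds
chronology reports the medians of the older and younger boundary draws and
carries no central age.  Collection-level age bounds take the most generous
envelope over all units, dated and stratigraphically inferred.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .calibration import ChronControl
from .phase_model import PosteriorSamples

__all__ = [
    "SampleAge",
    "Chronology",
    "EVENT_QUANTILES",
    "CHRONOLOGY_NAMES",
    "AGE_MODELS",
    "draw_quantile_from_old",
    "event_sample_ages",
    "bounds_sample_ages",
    "collection_age_bounds",
    "time_interval_label",
]

# from-old quantiles (older limit, central, younger limit) for the event chronology
EVENT_QUANTILES = (0.3173, 0.5, 0.6827)

CHRONOLOGY_NAMES = {"bounds": "Syverson-Blois: bounds", "event": "Syverson-Blois: event"}
AGE_MODELS = {"bounds": "Bayesian unit bounds", "event": "Bayesian event distribution"}

_PROVENANCES = {"direct", "rule_a", "rule_b", "rule_b1", "rule_c", "rule_d", "rule_e"}


@dataclass
class SampleAge:
    """One analysis-unit age row for a chronology."""

    analysis_unit_ref: str
    chronology_kind: str  # "event" | "bounds"
    age: Optional[int]
    agelimitolder: Optional[int]
    agelimityounger: Optional[int]
    provenance: str = "direct"

    def __post_init__(self) -> None:
        if self.chronology_kind not in ("event", "bounds"):
            raise ValueError(f"unknown chronology kind {self.chronology_kind!r}")
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if (
            self.agelimitolder is not None
            and self.agelimityounger is not None
            and self.agelimityounger > self.agelimitolder
        ):
            raise ValueError(
                f"unit {self.analysis_unit_ref}: younger limit {self.agelimityounger} "
                f"exceeds older limit {self.agelimitolder}"
            )
        if self.chronology_kind == "bounds" and self.age is not None:
            raise ValueError("bounds chronology rows carry no central age")
        if self.chronology_kind == "event" and self.provenance == "direct" and self.age is None:
            raise ValueError("direct event rows must carry a central age")
        if self.provenance != "direct" and self.age is not None:
            raise ValueError("inferred rows carry no central age")


@dataclass
class Chronology:
    """A full chronology for one collection unit (Neotoma `chronologies` row)."""

    collectionunit_ref: str
    kind: str  # "event" | "bounds"
    ageboundolder: Optional[int]
    ageboundyounger: Optional[int]
    sample_ages: List[SampleAge] = field(default_factory=list)
    controls: List[ChronControl] = field(default_factory=list)
    date_prepared: str = field(default_factory=lambda: _dt.date.today().isoformat())

    @property
    def name(self) -> str:
        return CHRONOLOGY_NAMES[self.kind]

    @property
    def agemodel(self) -> str:
        return AGE_MODELS[self.kind]


def draw_quantile_from_old(draws: np.ndarray, q_from_old: float) -> int:
    """From-old quantile of MCMC draws: mass at or above the result is ``q``."""
    if not (0.0 < q_from_old < 1.0):
        raise ValueError("q_from_old must be in (0, 1)")
    return int(round(float(np.quantile(np.asarray(draws, dtype=float), 1.0 - q_from_old))))


def event_sample_ages(samples: PosteriorSamples) -> List[SampleAge]:
    """Event-chronology rows: quantiles of each unit's predictive-age draws."""
    rows = []
    for j, uid in enumerate(samples.unit_ids):
        draws = samples.predictive_draws(j)
        older, central, younger = (draw_quantile_from_old(draws, q) for q in EVENT_QUANTILES)
        rows.append(
            SampleAge(
                analysis_unit_ref=uid,
                chronology_kind="event",
                age=central,
                agelimitolder=older,
                agelimityounger=younger,
            )
        )
    return rows


def bounds_sample_ages(samples: PosteriorSamples) -> List[SampleAge]:
    """Bounds-chronology rows: medians of the boundary draws, no central age."""
    rows = []
    for j, uid in enumerate(samples.unit_ids):
        older = draw_quantile_from_old(samples.alpha_draws(j), 0.5)
        younger = draw_quantile_from_old(samples.beta_draws(j), 0.5)
        rows.append(
            SampleAge(
                analysis_unit_ref=uid,
                chronology_kind="bounds",
                age=None,
                agelimitolder=older,
                agelimityounger=younger,
            )
        )
    return rows


def collection_age_bounds(sample_ages: List[SampleAge]) -> Tuple[Optional[int], Optional[int]]:
    """Overall (older, younger) envelope across all units, dated and inferred.

    Units with an undefined older limit contribute only their younger limit,
    and vice versa.
    """
    if not sample_ages:
        raise ValueError("collection bounds require at least one sample age")
    olders = [sa.agelimitolder for sa in sample_ages if sa.agelimitolder is not None]
    youngers = [sa.agelimityounger for sa in sample_ages if sa.agelimityounger is not None]
    return (max(olders) if olders else None, min(youngers) if youngers else None)


def time_interval_label(age: float) -> str:
    """Bin an age into LGM/DG/EH/LH; boundary ages fall in the older bin."""
    if age < 0 or age > 30_000:
        raise ValueError(f"age {age} outside 0-30,000 cal BP")
    if age >= 16_000:
        return "LGM"
    if age >= 11_700:
        return "DG"
    if age >= 6_000:
        return "EH"
    return "LH"
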