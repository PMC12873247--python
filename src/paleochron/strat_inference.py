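"""Infer age ranges for undated analysis units from stratigraphic context.

Rules (older limits always >= younger limits; ages in cal BP):

a.  subset of a dated unit -> copy that unit's range;
b.  bounded between dated units -> older limit from the top (younger bound)
    of the dated unit below, younger limit from the bottom (older bound) of
    the dated unit above;
b1. as (b) but the two dated ranges overlap (time-averaging) -> the union of
    the two dated ranges;
c.  above all dated units -> older limit from the top of the dated unit
    below, younger limit 0 unless externally constrained;
d.  below all dated units -> younger limit from the bottom of the dated unit
    above; older limit only from an external constraint (else undefined);
e.  no stratigraphic relationship -> the full envelope of all dated units;
f.  no central age is ever assigned.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Dict, List, Optional

from .chronology_builder import SampleAge
from .units import AnalysisUnit, CollectionUnit

__all__ = [
    "StratContext",
    "classify_undated_unit",
    "infer_undated_range",
    "infer_all_undated",
]

RELATIONS = ("subset_of_dated", "bounded_between", "above_all_dated", "below_all_dated", "unrelated")


@dataclass
class StratContext:
    """Stratigraphic relationship of one undated unit to its dated neighbours.

    Neighbour fields hold analysis-unit ids (resolved against a chronology's
    sample ages at inference time).
    """

    relation: str
    neighbor_below: Optional[str] = None  # next dated unit on the older side
    neighbor_above: Optional[str] = None  # next dated unit on the younger side
    container: Optional[str] = None  # dated unit this one is a subset of
    external_older_constraint: Optional[int] = None
    external_younger_constraint: Optional[int] = None

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        needs = {
            "subset_of_dated": self.container is not None,
            "bounded_between": self.neighbor_below is not None and self.neighbor_above is not None,
            "above_all_dated": self.neighbor_below is not None,
            "below_all_dated": self.neighbor_above is not None,
            "unrelated": True,
        }
        if not needs[self.relation]:
            raise ValueError(f"relation {self.relation!r} is missing its required neighbours")


def _position_key(cu: CollectionUnit, au: AnalysisUnit) -> Optional[float]:
    """Stratigraphic position, larger = older; None when unknown."""
    if au.depth is not None:
        return float(au.depth)
    if cu.declared_order is not None and au.id in cu.declared_order:
        # declared order runs oldest -> youngest
        return float(len(cu.declared_order) - cu.declared_order.index(au.id))
    return None


def classify_undated_unit(
    undated: AnalysisUnit,
    cu: CollectionUnit,
    external_older_constraint: Optional[int] = None,
    external_younger_constraint: Optional[int] = None,
) -> StratContext:
    """Classify an undated unit's relationship to the collection's dated units."""
    if undated.dates:
        raise ValueError(f"unit {undated.id} has dates; nothing to infer")
    dated = [au for au in cu.analysis_units if au.dates]
    dated_ids = {au.id for au in dated}

    if undated.subset_of is not None and undated.subset_of in dated_ids:
        return StratContext(
            relation="subset_of_dated",
            container=undated.subset_of,
            external_older_constraint=external_older_constraint,
            external_younger_constraint=external_younger_constraint,
        )

    pos = _position_key(cu, undated)
    if pos is not None:
        below: Optional[AnalysisUnit] = None  # nearest dated unit older than this one
        above: Optional[AnalysisUnit] = None  # nearest dated unit younger than this one
        for au in dated:
            p = _position_key(cu, au)
            if p is None:
                continue
            if p > pos and (below is None or p < _position_key(cu, below)):
                below = au
            elif p < pos and (above is None or p > _position_key(cu, above)):
                above = au
        if below is not None and above is not None:
            return StratContext(
                relation="bounded_between",
                neighbor_below=below.id,
                neighbor_above=above.id,
                external_older_constraint=external_older_constraint,
                external_younger_constraint=external_younger_constraint,
            )
        if below is not None:
            return StratContext(
                relation="above_all_dated",
                neighbor_below=below.id,
                external_older_constraint=external_older_constraint,
                external_younger_constraint=external_younger_constraint,
            )
        if above is not None:
            return StratContext(
                relation="below_all_dated",
                neighbor_above=above.id,
                external_older_constraint=external_older_constraint,
                external_younger_constraint=external_younger_constraint,
            )
    return StratContext(
        relation="unrelated",
        external_older_constraint=external_older_constraint,
        external_younger_constraint=external_younger_constraint,
    )


def _ranges_overlap(a: SampleAge, b: SampleAge) -> bool:
    """Closed-interval intersection of two [younger, older] ranges."""
    return a.agelimityounger <= b.agelimitolder and b.agelimityounger <= a.agelimitolder


def infer_undated_range(
    ctx: StratContext,
    dated: List[SampleAge],
    unit_id: str = "undated",
) -> SampleAge:
    """Apply rules a-f to produce the inferred SampleAge for one undated unit.

    ``dated`` holds the directly dated sample ages of one chronology; the
    result inherits that chronology's kind.
    """
    if not dated:
        raise ValueError("inference requires at least one dated sample age")
    kind = dated[0].chronology_kind
    by_id: Dict[str, SampleAge] = {sa.analysis_unit_ref: sa for sa in dated}

    def _lookup(uid: Optional[str], role: str) -> SampleAge:
        if uid is None or uid not in by_id:
            raise ValueError(f"relation {ctx.relation!r} requires a dated {role} unit")
        return by_id[uid]

    if ctx.relation == "subset_of_dated":
        container = _lookup(ctx.container, "containing")
        older, younger, rule = container.agelimitolder, container.agelimityounger, "rule_a"
    elif ctx.relation == "bounded_between":
        below = _lookup(ctx.neighbor_below, "below")
        above = _lookup(ctx.neighbor_above, "above")
        if _ranges_overlap(below, above):
            older = max(below.agelimitolder, above.agelimitolder)
            younger = min(below.agelimityounger, above.agelimityounger)
            rule = "rule_b1"
        else:
            older, younger, rule = below.agelimityounger, above.agelimitolder, "rule_b"
    elif ctx.relation == "above_all_dated":
        below = _lookup(ctx.neighbor_below, "below")
        older = below.agelimityounger
        younger = ctx.external_younger_constraint if ctx.external_younger_constraint is not None else 0
        rule = "rule_c"
    elif ctx.relation == "below_all_dated":
        above = _lookup(ctx.neighbor_above, "above")
        younger = above.agelimitolder
        older = ctx.external_older_constraint
        if older is None:
            _warnings.warn(
                f"unit {unit_id}: below all dated units with no external older "
                "constraint; older limit left undefined"
            )
        rule = "rule_d"
    else:  # unrelated
        older = max(sa.agelimitolder for sa in dated if sa.agelimitolder is not None)
        younger = min(sa.agelimityounger for sa in dated if sa.agelimityounger is not None)
        rule = "rule_e"

    return SampleAge(
        analysis_unit_ref=unit_id,
        chronology_kind=kind,
        age=None,  # rule f
        agelimitolder=older,
        agelimityounger=younger,
        provenance=rule,
    )


def infer_all_undated(
    cu: CollectionUnit,
    dated_sample_ages: List[SampleAge],
    external_constraints: Optional[Dict[str, Dict[str, int]]] = None,
) -> List[SampleAge]:
    """Infer sample ages for every undated unit in a collection.

    ``external_constraints`` maps unit id to ``{"older": ..., "younger": ...}``
    biostratigraphic/archeological constraints.
    """
    external_constraints = external_constraints or {}
    dated_ids = {sa.analysis_unit_ref for sa in dated_sample_ages}
    out: List[SampleAge] = []
    for au in cu.analysis_units:
        if au.id in dated_ids or au.dates:
            continue
        cons = external_constraints.get(au.id, {})
        ctx = classify_undated_unit(
            au,
            cu,
            external_older_constraint=cons.get("older"),
            external_younger_constraint=cons.get("younger"),
        )
        out.append(infer_undated_range(ctx, dated_sample_ages, unit_id=au.id))
    return out
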