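"""Stratigraphic container hierarchy: collection units and analysis units."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .calibration import GeochronDate

__all__ = ["AnalysisUnit", "CollectionUnit"]


@dataclass
class AnalysisUnit:
    """A sampling unit (usually a stratigraphic layer) within a collection.

    ``depth`` is metres below a local datum (deeper = older under
    superposition).  ``subset_of`` names a sibling unit this unit is a
    physical subset of (e.g. a single specimen drawn from a dated stratum).
    """

    id: str
    name: Optional[str] = None
    depth: Optional[float] = None
    dates: List[GeochronDate] = field(default_factory=list)
    subset_of: Optional[str] = None

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"analysis unit {self.id}: depth must be >= 0")


@dataclass
class CollectionUnit:
    """A collection of analysis units from one excavation/sampling effort.

    ``declared_order`` lists analysis-unit ids oldest to youngest when an
    explicit stratigraphic order is recorded.
    """

    id: str
    site_ref: Optional[str] = None
    analysis_units: List[AnalysisUnit] = field(default_factory=list)
    declared_order: Optional[List[str]] = None

    def __post_init__(self) -> None:
        ids = [au.id for au in self.analysis_units]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate analysis-unit ids in collection {self.id}: {dupes}")
        if self.declared_order is not None:
            unknown = set(self.declared_order) - set(ids)
            if unknown:
                raise ValueError(f"declared_order references unknown units: {sorted(unknown)}")

    def unit(self, unit_id: str) -> AnalysisUnit:
        for au in self.analysis_units:
            if au.id == unit_id:
                return au
        raise KeyError(unit_id)
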