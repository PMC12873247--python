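"""Read collection-unit records, apply the date filters, write chronology tables.

Local fixtures are JSON (nested collection -> analysis units -> dates) or
flat CSV (one row per date; rows without date fields declare undated units).
A thin, optional API client can fetch live records; all tests and offline
runs use fixtures.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .calibration import ChronControl, GeochronDate
from .units import AnalysisUnit, CollectionUnit

__all__ = [
    "read_collection",
    "filter_geochron_dates",
    "select_collection",
    "write_chronology_tables",
    "read_chronology_tables",
    "emit_oxcal_script",
    "RADIOCARBON_MAX_C14_BP",
    "MODERN_AGE_CUTOFF",
]

RADIOCARBON_MAX_C14_BP = 30_000  # selection predicate: (age - error_minus) must be below this
MODERN_AGE_CUTOFF = 10

NEOTOMA_API = "https://api.neotomadb.org/v2.0"

_CALENDAR_TYPES = {
    "calendar", "tl", "thermoluminescence", "osl", "uranium-series", "u-series",
    "argon-argon", "ar-ar", "paleomagnetic", "calibrated radiocarbon",
}


def _date_from_record(rec: dict) -> GeochronDate:
    err = rec.get("error")
    e_minus = rec.get("error_minus", err)
    e_plus = rec.get("error_plus", err)
    kind = str(rec.get("kind", "radiocarbon")).lower()
    if kind not in ("radiocarbon", "calendar"):
        kind = "calendar" if kind in _CALENDAR_TYPES else "radiocarbon"
    return GeochronDate(
        age=float(rec["age"]),
        error_minus=float(e_minus if e_minus is not None else 0.0),
        error_plus=float(e_plus if e_plus is not None else 0.0),
        kind=kind,
        lab_id=rec.get("lab_id") or rec.get("labnumber"),
        material=rec.get("material"),
        method=rec.get("method"),
        rejected=bool(rec.get("rejected", False)),
        human_remains=bool(rec.get("human_remains", False)),
        single_sided=bool(rec.get("single_sided", False)),
    )


def _collection_from_dict(doc: dict) -> CollectionUnit:
    try:
        units = []
        for u in doc.get("analysis_units", []):
            units.append(
                AnalysisUnit(
                    id=str(u["id"]),
                    name=u.get("name"),
                    depth=None if u.get("depth") is None else float(u["depth"]),
                    subset_of=u.get("subset_of"),
                    dates=[_date_from_record(d) for d in u.get("dates", [])],
                )
            )
        return CollectionUnit(
            id=str(doc["id"]),
            site_ref=None if doc.get("site_ref") is None else str(doc["site_ref"]),
            analysis_units=units,
            declared_order=[str(x) for x in doc["declared_order"]] if doc.get("declared_order") else None,
        )
    except KeyError as exc:
        raise ValueError(f"malformed collection record: missing field {exc}") from None


def _collection_from_csv(path: Union[str, Path]) -> CollectionUnit:
    df = pd.read_csv(path)
    required = {"collectionunitid", "analysisunitid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"malformed CSV fixture: missing columns {sorted(missing)}")
    cu_ids = df["collectionunitid"].unique()
    if len(cu_ids) != 1:
        raise ValueError("CSV fixture must describe exactly one collection unit")
    units: Dict[str, AnalysisUnit] = {}
    for _, row in df.iterrows():
        uid = str(row["analysisunitid"])
        if uid not in units:
            depth = row.get("depth")
            units[uid] = AnalysisUnit(
                id=uid,
                name=str(row["analysisunitname"]) if "analysisunitname" in df.columns and pd.notna(row.get("analysisunitname")) else None,
                depth=float(depth) if depth is not None and pd.notna(depth) else None,
                subset_of=str(row["subsetof"]) if "subsetof" in df.columns and pd.notna(row.get("subsetof")) else None,
            )
        if "age" in df.columns and pd.notna(row.get("age")):
            rec = {
                "age": row["age"],
                "error_minus": row.get("erroryounger") if pd.notna(row.get("erroryounger")) else row.get("error"),
                "error_plus": row.get("errorolder") if pd.notna(row.get("errorolder")) else row.get("error"),
                "kind": row.get("datetype", "radiocarbon") if pd.notna(row.get("datetype")) else "radiocarbon",
                "labnumber": row.get("labnumber") if pd.notna(row.get("labnumber")) else None,
                "rejected": bool(row.get("rejected", False)) if pd.notna(row.get("rejected")) else False,
                "human_remains": bool(row.get("humanremains", False)) if pd.notna(row.get("humanremains")) else False,
                "single_sided": bool(row.get("singlesided", False)) if pd.notna(row.get("singlesided")) else False,
            }
            units[uid].dates.append(_date_from_record(rec))
    return CollectionUnit(
        id=str(cu_ids[0]),
        site_ref=str(df["siteid"].iloc[0]) if "siteid" in df.columns else None,
        analysis_units=list(units.values()),
    )


def _default_fetcher(url: str) -> dict:
    from urllib.request import urlopen

    with urlopen(url, timeout=60) as resp:
        return json.loads(resp.read().decode("utf-8"))


def _collection_from_api(
    locator: str,
    cache_dir: Optional[Union[str, Path]] = None,
    fetcher: Optional[Callable[[str], dict]] = None,
) -> CollectionUnit:
    """Fetch a collection's geochronology from the Neotoma API.

    ``locator`` is ``"neotoma:<siteid>"``.  Responses are cached to
    ``cache_dir`` (JSON) and reused on later calls, so a previously fetched
    collection remains readable offline.
    """
    siteid = locator.split(":", 1)[1]
    fetcher = fetcher or _default_fetcher
    cache_path = Path(cache_dir) / f"neotoma_site_{siteid}.json" if cache_dir else None
    if cache_path is not None and cache_path.exists():
        doc = json.loads(cache_path.read_text())
    else:
        doc = fetcher(f"{NEOTOMA_API}/data/sites/{siteid}/collectionunits/geochronology")
        if cache_path is not None:
            cache_path.parent.mkdir(parents=True, exist_ok=True)
            cache_path.write_text(json.dumps(doc))
    # accept either our fixture shape or an API envelope {"data": {...}}
    payload = doc.get("data", doc)
    if isinstance(payload, list):
        payload = payload[0]
    if "analysis_units" in payload:
        return _collection_from_dict(payload)
    raise ValueError(f"unrecognized API payload for site {siteid}")


def read_collection(
    source: Union[str, Path, dict],
    cache_dir: Optional[Union[str, Path]] = None,
    fetcher: Optional[Callable[[str], dict]] = None,
) -> CollectionUnit:
    """Load a collection unit from a dict, JSON/CSV fixture path, or API locator.

    API locators look like ``"neotoma:3534"`` and are the only inputs that
    touch the network (responses cached under ``cache_dir``).
    """
    if isinstance(source, dict):
        return _collection_from_dict(source)
    text = str(source)
    if text.startswith("neotoma:"):
        return _collection_from_api(text, cache_dir=cache_dir, fetcher=fetcher)
    path = Path(text)
    if not path.exists():
        raise FileNotFoundError(f"collection source not found: {path}")
    if path.suffix.lower() == ".csv":
        return _collection_from_csv(path)
    return _collection_from_dict(json.loads(path.read_text()))


def filter_geochron_dates(
    dates: Sequence[GeochronDate],
    scan_keywords: bool = False,
) -> Tuple[List[GeochronDate], List[Tuple[GeochronDate, str]]]:
    """Apply the usability filters, returning (usable, excluded-with-reason).

    Exclusion reasons, in precedence order: ``single_sided``, ``modern``
    (stored age <= 10), ``zero_error`` (missing or zero on either side),
    ``rejected``, ``human_remains``.  With ``scan_keywords`` the material and
    method strings are scanned for "reject"/"human" markers.
    """
    usable: List[GeochronDate] = []
    excluded: List[Tuple[GeochronDate, str]] = []
    for d in dates:
        rejected = d.rejected
        human = d.human_remains
        if scan_keywords:
            text = " ".join(filter(None, [d.material, d.method])).lower()
            rejected = rejected or "reject" in text
            human = human or "human" in text
        if d.single_sided:
            excluded.append((d, "single_sided"))
        elif d.age <= MODERN_AGE_CUTOFF:
            excluded.append((d, "modern"))
        elif d.error_minus <= 0 or d.error_plus <= 0:
            excluded.append((d, "zero_error"))
        elif rejected:
            excluded.append((d, "rejected"))
        elif human:
            excluded.append((d, "human_remains"))
        else:
            usable.append(d)
    return usable, excluded


def select_collection(cu: CollectionUnit, scan_keywords: bool = False) -> bool:
    """Eligibility: at least one usable radiocarbon date whose younger 1-sigma
    age (age minus error_minus) lies below 30,000 14C BP."""
    for au in cu.analysis_units:
        usable, _ = filter_geochron_dates(au.dates, scan_keywords=scan_keywords)
        for d in usable:
            if d.kind == "radiocarbon" and (d.age - d.error_minus) < RADIOCARBON_MAX_C14_BP:
                return True
    return False


# ---------------------------------------------------------------------------
# chronology table writers (Neotoma three-table layout)

_CHRONOLOGY_COLS = [
    "chronologyid", "collectionunitid", "chronologyname", "agemodel",
    "ageboundolder", "ageboundyounger", "dateprepared",
]
_SAMPLEAGE_COLS = [
    "sampleageid", "chronologyid", "analysisunitid", "agemodel",
    "age", "agelimitolder", "agelimityounger", "provenance",
]
_CHRONCONTROL_COLS = [
    "chroncontrolid", "chronologyid", "analysisunitid", "labnumber",
    "age", "agelimitolder", "agelimityounger", "controltype",
    "geochronage", "geochronerrorolder", "geochronerroryounger", "geochronkind",
]


def write_chronology_tables(chronologies: Sequence, dest: Union[str, Path]) -> Dict[str, Path]:
    """Write chronologies/sampleages/chroncontrols CSVs under ``dest``.

    Temporary ids are assigned monotonically from 1.  Returns the paths.
    The ``geochron*`` columns are extra (non-Neotoma) fields that make the
    tables round-trippable.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    chron_rows, sa_rows, cc_rows = [], [], []
    next_sa, next_cc = 1, 1
    for cid, ch in enumerate(chronologies, start=1):
        chron_rows.append({
            "chronologyid": cid,
            "collectionunitid": ch.collectionunit_ref,
            "chronologyname": ch.name,
            "agemodel": ch.agemodel,
            "ageboundolder": ch.ageboundolder,
            "ageboundyounger": ch.ageboundyounger,
            "dateprepared": ch.date_prepared,
        })
        for sa in ch.sample_ages:
            sa_rows.append({
                "sampleageid": next_sa,
                "chronologyid": cid,
                "analysisunitid": sa.analysis_unit_ref,
                "agemodel": sa.chronology_kind,
                "age": sa.age,
                "agelimitolder": sa.agelimitolder,
                "agelimityounger": sa.agelimityounger,
                "provenance": sa.provenance,
            })
            next_sa += 1
        for cc in ch.controls:
            ref = cc.geochron_ref
            cc_rows.append({
                "chroncontrolid": next_cc,
                "chronologyid": cid,
                "analysisunitid": getattr(cc, "analysis_unit_ref", None),
                "labnumber": ref.lab_id,
                "age": cc.age,
                "agelimitolder": cc.agelimitolder,
                "agelimityounger": cc.agelimityounger,
                "controltype": cc.control_type,
                "geochronage": ref.age,
                "geochronerrorolder": ref.error_plus,
                "geochronerroryounger": ref.error_minus,
                "geochronkind": ref.kind,
            })
            next_cc += 1
    paths = {}
    for name, rows, cols in [
        ("chronologies", chron_rows, _CHRONOLOGY_COLS),
        ("sampleages", sa_rows, _SAMPLEAGE_COLS),
        ("chroncontrols", cc_rows, _CHRONCONTROL_COLS),
    ]:
        path = dest / f"{name}.csv"
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        paths[name] = path
    return paths


def read_chronology_tables(src: Union[str, Path]) -> List:
    """Read the three-table layout back into Chronology objects."""
    from .chronology_builder import AGE_MODELS, Chronology, SampleAge

    src = Path(src)
    chron = pd.read_csv(src / "chronologies.csv")
    sa = pd.read_csv(src / "sampleages.csv")
    cc = pd.read_csv(src / "chroncontrols.csv")
    kind_by_model = {v: k for k, v in AGE_MODELS.items()}
    out = []
    for _, row in chron.iterrows():
        kind = kind_by_model[row["agemodel"]]
        sample_ages = []
        for _, s in sa[sa["chronologyid"] == row["chronologyid"]].iterrows():
            sample_ages.append(SampleAge(
                analysis_unit_ref=str(s["analysisunitid"]),
                chronology_kind=str(s["agemodel"]),
                age=None if pd.isna(s["age"]) else int(s["age"]),
                agelimitolder=None if pd.isna(s["agelimitolder"]) else int(s["agelimitolder"]),
                agelimityounger=None if pd.isna(s["agelimityounger"]) else int(s["agelimityounger"]),
                provenance=str(s["provenance"]),
            ))
        controls = []
        for _, c in cc[cc["chronologyid"] == row["chronologyid"]].iterrows():
            ref = GeochronDate(
                age=float(c["geochronage"]),
                error_minus=float(c["geochronerroryounger"]),
                error_plus=float(c["geochronerrorolder"]),
                kind=str(c["geochronkind"]),
                lab_id=None if pd.isna(c["labnumber"]) else str(c["labnumber"]),
            )
            controls.append(ChronControl(
                geochron_ref=ref,
                age=int(c["age"]),
                agelimitolder=int(c["agelimitolder"]),
                agelimityounger=int(c["agelimityounger"]),
                control_type=str(c["controltype"]),
                analysis_unit_ref=None if pd.isna(c["analysisunitid"]) else str(c["analysisunitid"]),
            ))
        out.append(Chronology(
            collectionunit_ref=str(row["collectionunitid"]),
            kind=kind,
            ageboundolder=None if pd.isna(row["ageboundolder"]) else int(row["ageboundolder"]),
            ageboundyounger=None if pd.isna(row["ageboundyounger"]) else int(row["ageboundyounger"]),
            sample_ages=sample_ages,
            controls=controls,
            date_prepared=str(row["dateprepared"]),
        ))
    return out


# ---------------------------------------------------------------------------
# OxCal script generation

def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else str(x)


def emit_oxcal_script(cu: CollectionUnit, ordered: Optional[bool] = None) -> str:
    """Emit an OxCal v4.4 script for a collection's dated analysis units.

    Each dated unit becomes a ``Boundary(); Phase{dates...; Date();};
    Boundary();`` block, wrapped in ``Sequence()`` when ordered (phases
    oldest to youngest) and in an unordered ``Phase()`` otherwise.
    Deterministic formatting; asymmetric errors are averaged for ``R_Date``.
    """
    from .phase_model import infer_order

    dated = [au for au in cu.analysis_units if any(
        not d.single_sided and d.error_minus > 0 and d.error_plus > 0 for d in au.dates
    )]
    if not dated:
        raise ValueError(f"collection {cu.id} has no dated analysis units to script")
    inferred_ordered, order_ids = infer_order(cu, [au.id for au in dated])
    if ordered is None:
        ordered = inferred_ordered
    by_id = {au.id: au for au in dated}
    sequence = [by_id[uid] for uid in order_ids] if ordered else dated

    lines: List[str] = ["Plot()", "{"]
    outer = "Sequence" if ordered else "Phase"
    lines.append(f' {outer}("{cu.id}")')
    lines.append(" {")
    for au in sequence:
        label = au.name or au.id
        lines.append(f'  Boundary("start {label}");')
        lines.append(f'  Phase("{label}")')
        lines.append("  {")
        for d in au.dates:
            if d.single_sided or d.error_minus <= 0 or d.error_plus <= 0:
                continue
            err = _fmt_num((d.error_minus + d.error_plus) / 2.0)
            lab = d.lab_id or "unknown"
            call = "R_Date" if d.kind == "radiocarbon" else "C_Date"
            lines.append(f'   {call}("{lab}",{_fmt_num(d.age)},{err});')
        lines.append(f'   Date("{label} event");')
        lines.append("  };")
        lines.append(f'  Boundary("end {label}");')
    lines.append(" };")
    lines.append("};")
    return "\n".join(lines) + "\n"
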