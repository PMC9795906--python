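"""Cascade assignment of sequences and OTUs to biogeographic areas.

Assignment order per sequence: (1) recorded country, if it maps to exactly
one area; (2) sampling coordinates falling in exactly one area polygon;
(3) a manually curated area code (standing in for non-reproducible web
geocoding, at the same cascade position); (4) unassigned.  OTU areas are the
union over member sequences, with introduced occurrences removable via
per-OTU overrides.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, shape
from shapely.prepared import prep

from areaevo.io_core import MetadataRecord

logger = logging.getLogger(__name__)

DEFAULT_AREAS = ["And", "CAm", "Pat", "TSA", "Afr", "Aus", "Ind", "Nea", "Pal"]
FOCAL_AREAS = ["And", "CAm", "Pat", "TSA"]

__all__ = [
    "DEFAULT_AREAS",
    "FOCAL_AREAS",
    "AreaScheme",
    "SequenceAssignment",
    "OverlappingAreasError",
    "assign_sequence",
    "assign_otu",
    "assign_all",
    "area_summary",
    "otu_overlap",
    "load_default_country_table",
]


class OverlappingAreasError(ValueError):
    """Coordinates fall inside more than one area polygon."""


@dataclass
class AreaScheme:
    """Area codes, their polygons, and the country -> areas lookup."""

    area_codes: list[str]
    polygons: dict  # area code -> shapely geometry (may be missing areas)
    country_table: dict[str, list[str]]

    def __post_init__(self):
        if len(set(self.area_codes)) != len(self.area_codes):
            raise ValueError("area codes must be unique")
        for code, geom in self.polygons.items():
            if code not in self.area_codes:
                raise ValueError(f"polygon for unknown area {code!r}")
            if not geom.is_valid:
                raise ValueError(f"invalid polygon for area {code!r}")
        for country, areas in self.country_table.items():
            unknown = set(areas) - set(self.area_codes)
            if unknown:
                raise ValueError(f"country {country!r} maps to unknown areas {unknown}")
        self._prepared = {c: prep(g) for c, g in self.polygons.items()}

    @classmethod
    def from_files(cls, geojson_path=None, countries_path=None, area_codes=None):
        polygons = {}
        if geojson_path is not None:
            fc = json.loads(Path(geojson_path).read_text())
            if fc.get("type") != "FeatureCollection":
                raise ValueError("areas GeoJSON must be a FeatureCollection")
            for feat in fc["features"]:
                code = feat["properties"].get("area") or feat["properties"].get("name")
                if code is None:
                    raise ValueError("each feature needs an 'area' property")
                polygons[code] = shape(feat["geometry"])
        if countries_path is not None:
            table = yaml.safe_load(Path(countries_path).read_text()) or {}
        else:
            table = load_default_country_table()
        table = {c: list(v) if isinstance(v, (list, tuple)) else [v] for c, v in table.items()}
        if area_codes is None:
            codes = list(dict.fromkeys(
                list(polygons) + [a for v in table.values() for a in v]
            )) or list(DEFAULT_AREAS)
        else:
            codes = list(area_codes)
        return cls(area_codes=codes, polygons=polygons, country_table=table)

    def areas_containing(self, lat: float, lon: float) -> list[str]:
        """Areas whose polygon covers the point; boundary points are inside."""
        pt = Point(lon, lat)
        hits = []
        for code in self.area_codes:
            g = self._prepared.get(code)
            if g is not None and g.intersects(pt) and self.polygons[code].covers(pt):
                hits.append(code)
        return hits


def load_default_country_table() -> dict[str, list[str]]:
    text = resources.files("areaevo").joinpath("data/countries.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class SequenceAssignment:
    sequence_id: str
    otu_id: Optional[str]
    area: Optional[str]
    provenance: str  # country | coordinates | manual | none


def assign_sequence(record: MetadataRecord, scheme: AreaScheme) -> SequenceAssignment:
    """Run the assignment cascade for one sequence."""
    if record.country is not None:
        areas = scheme.country_table.get(record.country)
        if areas is not None and len(areas) == 1:
            return SequenceAssignment(record.sequence_id, record.otu_id, areas[0], "country")
    if record.lat is not None and record.lon is not None:
        hits = scheme.areas_containing(record.lat, record.lon)
        if len(hits) > 1:
            raise OverlappingAreasError(
                f"point ({record.lat}, {record.lon}) of {record.sequence_id!r} "
                f"falls in overlapping areas: {hits}"
            )
        if len(hits) == 1:
            return SequenceAssignment(record.sequence_id, record.otu_id, hits[0], "coordinates")
    if record.manual_area is not None:
        if record.manual_area not in scheme.area_codes:
            raise ValueError(
                f"manual area {record.manual_area!r} of {record.sequence_id!r} unknown"
            )
        return SequenceAssignment(record.sequence_id, record.otu_id, record.manual_area, "manual")
    return SequenceAssignment(record.sequence_id, record.otu_id, None, "none")


def assign_otu(
    members: Sequence[SequenceAssignment],
    overrides: Sequence[tuple[str, str]] = (),
) -> set[str]:
    """Union of member areas minus introduced-occurrence overrides."""
    otus = {m.otu_id for m in members}
    if len(otus) > 1:
        raise ValueError(f"members belong to several OTUs: {sorted(map(str, otus))}")
    areas = {m.area for m in members if m.area is not None}
    otu = next(iter(otus)) if otus else None
    for o_id, area in overrides:
        if o_id != otu:
            continue
        if area in areas:
            areas.discard(area)
            logger.info("ignored introduced occurrence of OTU %s in %s", otu, area)
        else:
            logger.warning("override for OTU %s names area %s not in its union", otu, area)
    return areas


def assign_all(
    records: Sequence[MetadataRecord],
    scheme: AreaScheme,
    overrides: Sequence[tuple[str, str]] = (),
) -> tuple[list[SequenceAssignment], dict[str, set[str]]]:
    """Assign every sequence, then union per OTU (keyed by otu_id)."""
    seq_assignments = [assign_sequence(r, scheme) for r in records]
    by_otu: dict[str, list[SequenceAssignment]] = {}
    for a in seq_assignments:
        if a.otu_id is not None:
            by_otu.setdefault(a.otu_id, []).append(a)
    otu_areas = {otu: assign_otu(ms, overrides) for otu, ms in by_otu.items()}
    return seq_assignments, otu_areas


def area_summary(
    seq_assignments: Sequence[SequenceAssignment],
    otu_areas: dict[str, set[str]],
    area_codes: Sequence[str] = DEFAULT_AREAS,
) -> pd.DataFrame:
    """Counts and percentages of sequences and OTUs per area plus unassigned.

    Percentages are over the grand totals, so OTU percentages may sum above
    100 (one OTU can occur in several areas).
    """
    n_seq = len(seq_assignments)
    n_otu = len(otu_areas)
    rows = []
    for code in area_codes:
        s = sum(1 for a in seq_assignments if a.area == code)
        o = sum(1 for areas in otu_areas.values() if code in areas)
        rows.append((code, s, o))
    s_un = sum(1 for a in seq_assignments if a.area is None)
    o_un = sum(1 for areas in otu_areas.values() if not areas)
    rows.append(("unassigned", s_un, o_un))
    df = pd.DataFrame(rows, columns=["area", "sequences", "otus"])
    df["sequences_pct"] = 100.0 * df["sequences"] / n_seq if n_seq else 0.0
    df["otus_pct"] = 100.0 * df["otus"] / n_otu if n_otu else 0.0
    return df


def otu_overlap(
    otu_areas: dict[str, set[str]],
    area_codes: Sequence[str] = DEFAULT_AREAS,
) -> pd.DataFrame:
    """Symmetric area x area matrix of shared-OTU counts (diagonal = per-area OTUs)."""
    k = len(area_codes)
    idx = {c: i for i, c in enumerate(area_codes)}
    mat = np.zeros((k, k), dtype=int)
    for areas in otu_areas.values():
        present = sorted(idx[a] for a in areas if a in idx)
        for i in present:
            for j in present:
                mat[i, j] += 1
    return pd.DataFrame(mat, index=list(area_codes), columns=list(area_codes))
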