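"""Biogeography summaries of containment hit tables.

Turns a hit table into per-query threshold counts (hits above 75/50/25/5%
containment plus total hits with any containment), joins per-sample
geographic metadata, counts geographically distinct locations above a
containment threshold, and exports map-ready GeoJSON points.

"Geographically distinct" is this package's operational definition:
location keys are the case-folded, whitespace-normalized location label
when present, else (latitude, longitude) rounded to 0.1°, else a shared
"unknown" bucket.  All threshold comparisons are strict (> t).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "read_metadata",
    "summarize_thresholds",
    "join_metadata",
    "count_distinct_locations",
    "threshold_summary",
    "export_map_points",
    "write_geojson",
    "read_geojson",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.75, 0.50, 0.25, 0.05)

METADATA_COLUMNS = ["subject_id", "location_label", "latitude", "longitude"]


def _check_thresholds(thresholds: Sequence[float]) -> list[float]:
    ts = list(thresholds)
    if not ts:
        raise ValueError("at least one threshold required")
    if any(not 0.0 < t < 1.0 for t in ts):
        raise ValueError(f"thresholds must lie in (0,1): {ts}")
    if any(ts[i] <= ts[i + 1] for i in range(len(ts) - 1)):
        raise ValueError(f"thresholds must be strictly descending: {ts}")
    return ts


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-separated sample metadata table.

    Requires subject_id; validates coordinate ranges and that latitude and
    longitude are either both present or both absent per row.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    if "subject_id" not in table.columns:
        raise ValueError("metadata table missing column 'subject_id'")
    for col in ("location_label", "latitude", "longitude", "environment_note"):
        if col not in table.columns:
            table[col] = pd.NA
    table["latitude"] = pd.to_numeric(table["latitude"], errors="raise")
    table["longitude"] = pd.to_numeric(table["longitude"], errors="raise")
    lat, lon = table["latitude"], table["longitude"]
    if ((lat < -90) | (lat > 90)).any():
        raise ValueError("latitude out of [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise ValueError("longitude out of [-180, 180]")
    if (lat.isna() != lon.isna()).any():
        raise ValueError("latitude and longitude must be both present or both absent")
    return table


def summarize_thresholds(
    hits: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    queries: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-query cumulative hit counts with strict ">" at each threshold.

    Columns: ``query_name``, ``hits_gt_<pct>pct`` per threshold (descending),
    ``total_hits`` (containment > 0).  ``queries`` forces rows (all zero) for
    queries absent from the hit table.
    """
    ts = _check_thresholds(thresholds)
    if queries is None:
        queries = list(dict.fromkeys(hits["query_name"])) if len(hits) else []
    rows = []
    for q in queries:
        sub = hits[hits["query_name"] == q] if len(hits) else hits
        row: dict[str, object] = {"query_name": q}
        for t in ts:
            row[_threshold_col(t)] = int((sub["containment"] > t).sum()) if len(sub) else 0
        row["total_hits"] = int((sub["containment"] > 0).sum()) if len(sub) else 0
        rows.append(row)
    cols = ["query_name"] + [_threshold_col(t) for t in ts] + ["total_hits"]
    return pd.DataFrame(rows, columns=cols)


def _threshold_col(t: float) -> str:
    pct = 100 * t
    label = f"{pct:g}".replace(".", "_")
    return f"hits_gt_{label}pct"


def join_metadata(hits: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Left-join metadata onto hits by subject_id.

    Hits without metadata are retained and flagged (``has_metadata`` False),
    never dropped; duplicate subject_id in the metadata is an error naming
    the accession.
    """
    dup = metadata["subject_id"][metadata["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id in metadata: {dup.iloc[0]!r}")
    meta_cols = [c for c in metadata.columns if c == "subject_id" or c not in hits.columns]
    annotated = hits.merge(
        metadata[meta_cols], on="subject_id", how="left", indicator="_merge"
    )
    annotated["has_metadata"] = annotated.pop("_merge") == "both"
    assert len(annotated) == len(hits)  # left join on unique keys preserves rows
    return annotated


def _location_key(row: pd.Series) -> str:
    label = row.get("location_label")
    if isinstance(label, str) and label.strip():
        return " ".join(label.casefold().split())
    lat, lon = row.get("latitude"), row.get("longitude")
    if pd.notna(lat) and pd.notna(lon):
        # 0.1-degree grid; +0.0 normalizes -0.0
        return f"{round(float(lat), 1) + 0.0:.1f},{round(float(lon), 1) + 0.0:.1f}"
    return "unknown"


def count_distinct_locations(annotated: pd.DataFrame, threshold: float = 0.25) -> int:
    """Distinct location keys among hits with containment > threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold out of [0,1]: {threshold}")
    above = annotated[annotated["containment"] > threshold]
    if len(above) == 0:
        return 0
    return above.apply(_location_key, axis=1).nunique()


def threshold_summary(
    annotated: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    distinct_threshold: float = 0.25,
    queries: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Full per-query summary: threshold counts, total hits, and distinct
    locations above ``distinct_threshold`` — one row per query."""
    summary = summarize_thresholds(annotated, thresholds, queries=queries)
    col = f"distinct_locations_gt_{f'{100 * distinct_threshold:g}'.replace('.', '_')}pct"
    counts = []
    for q in summary["query_name"]:
        sub = annotated[annotated["query_name"] == q]
        counts.append(count_distinct_locations(sub, distinct_threshold))
    summary[col] = counts
    return summary


def export_map_points(
    annotated: pd.DataFrame, min_containment: float = 0.10
) -> dict:
    """GeoJSON FeatureCollection of hits with coordinates and containment
    strictly above ``min_containment`` (WGS84 longitude-latitude order).

    Hits without coordinates are excluded with a logged count.
    """
    if not 0.0 <= min_containment <= 1.0:
        raise ValueError(f"min_containment out of [0,1]: {min_containment}")
    above = annotated[annotated["containment"] > min_containment]
    has_coords = above["latitude"].notna() & above["longitude"].notna()
    n_dropped = int((~has_coords).sum())
    if n_dropped:
        logger.info(
            "export_map_points: %d hit(s) above %.2f lacked coordinates and were "
            "excluded", n_dropped, min_containment,
        )
    above = above[has_coords].sort_values(
        ["query_name", "subject_id"], kind="mergesort"
    )
    features = []
    for row in above.itertuples(index=False):
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(row.longitude), float(row.latitude)],
                },
                "properties": {
                    "query_name": row.query_name,
                    "subject_id": row.subject_id,
                    "containment": round(float(row.containment), 4),
                    "cani": round(float(row.cani), 4),
                    "location_label": (
                        row.location_label
                        if isinstance(row.location_label, str)
                        else None
                    ),
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(collection: dict, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(collection, indent=1, sort_keys=True, allow_nan=False) + "\n"
    )


def read_geojson(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    return doc
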