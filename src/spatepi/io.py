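"""Readers and writers for the pipeline's plain-text formats.

Area tables and edge lists travel as CSV; diagnostics as JSON; cluster
memberships optionally as GeoJSON point features. When an area CSV carries
two census population columns (``pop2006``, ``pop2011``) the population at
risk is their arithmetic mean; a single ``pop`` column is used as-is.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .incidence import validate_area_table


class SchemaError(ValueError):
    """An input file is missing a required column."""


def read_area_table(path) -> pd.DataFrame:
    """Read and validate an area CSV.

    Required columns: ``id``, ``x``, ``y``, ``cases`` and either ``pop`` or
    both ``pop2006`` and ``pop2011`` (averaged into ``pop``).
    """
    df = pd.read_csv(path)
    for col in ("id", "x", "y", "cases"):
        if col not in df.columns:
            raise SchemaError(f"area file {path}: missing required column {col!r}")
    if "pop" not in df.columns:
        if {"pop2006", "pop2011"} <= set(df.columns):
            df["pop"] = (df["pop2006"] + df["pop2011"]) / 2.0
        else:
            raise SchemaError(
                f"area file {path}: need a 'pop' column or both 'pop2006' and 'pop2011'"
            )
    return validate_area_table(df)


def write_area_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_edges(path) -> pd.DataFrame:
    """Two-column undirected edge-list CSV (header ``id_a,id_b``)."""
    df = pd.read_csv(path)
    for col in ("id_a", "id_b"):
        if col not in df.columns:
            raise SchemaError(f"edge file {path}: missing required column {col!r}")
    return df[["id_a", "id_b"]]


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, index=False)


def geojson_to_edges(path) -> pd.DataFrame:
    """Queen-contiguity edge list from a polygon FeatureCollection.

    Features must carry an ``id`` property; two polygons are neighbours when
    their boundaries share at least one point (queen rule).
    """
    from shapely.geometry import shape

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"]
    ids = []
    geoms = []
    for f in feats:
        props = f.get("properties") or {}
        if "id" not in props:
            raise SchemaError(f"GeoJSON {path}: feature without an 'id' property")
        ids.append(props["id"])
        geoms.append(shape(f["geometry"]))
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if geoms[i].intersects(geoms[j]):
                edges.append((ids[i], ids[j]))
    return pd.DataFrame(edges, columns=["id_a", "id_b"])


def clusters_to_geojson(clusters, areas: pd.DataFrame, path) -> None:
    """Write cluster memberships as a FeatureCollection of area centroids."""
    lookup = areas.set_index("id")
    feats = []
    for cl in clusters:
        for aid in cl.window.member_ids:
            row = lookup.loc[aid]
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [float(row["x"]), float(row["y"])]},
                    "properties": {
                        "id": aid if not hasattr(aid, "item") else aid.item(),
                        "cluster_rank": cl.rank,
                        "direction": cl.direction,
                        "cluster_center": cl.window.center_id,
                    },
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, default=str)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
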