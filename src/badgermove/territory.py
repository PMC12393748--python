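"""Convex-hull summaries of metastable clusters and social-group ranges.

A convex hull — the smallest convex polygon containing a point set — is
used as a simple, interpretable outline of space use: one hull per
metastable cluster (from the Koopman partition) and one per social group
(all fixes of the group's members).  Cluster and group hull families are
compared per subset (site, capture year, pooled) by count and by mean
(SD) hull area in km².
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Polygon, mapping

M2_PER_KM2 = 1e6


@dataclass
class HullSummary:
    """Convex hull of one cluster's or group's fixes."""

    label: str
    role: str                 # "cluster" | "group"
    vertices: np.ndarray      # (k, 2) counter-clockwise, subset of members
    area_km2: float
    n_fixes: int

    @property
    def polygon(self) -> Polygon | None:
        return Polygon(self.vertices) if len(self.vertices) >= 3 else None


def convex_hull_area(points, label: str = "", role: str = "cluster") -> HullSummary:
    """Convex hull and its area in km².

    Fewer than three distinct non-collinear points cannot enclose area;
    such degenerate sets yield a zero-area hull with a warning rather
    than an error (sparse clusters are reported, not dropped).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        warnings.warn(f"empty point set for hull {label!r}")
        return HullSummary(label, role, np.empty((0, 2)), 0.0, 0)
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":  # point or line: zero area
        warnings.warn(f"degenerate hull for {label!r}: "
                      f"{len(pts)} point(s), geometry {hull.geom_type}")
        verts = np.atleast_2d(np.asarray(hull.coords if hasattr(hull, "coords")
                                         else [], dtype=float))
        return HullSummary(label, role, verts.reshape(-1, 2), 0.0, len(pts))
    verts = np.asarray(hull.exterior.coords[:-1], dtype=float)
    return HullSummary(label, role, verts, hull.area / M2_PER_KM2, len(pts))


def _hull_family(fixes: pd.DataFrame, labels: np.ndarray, role: str) -> list[HullSummary]:
    out = []
    for lab in np.unique(labels):
        if lab == 0 and role == "cluster":
            continue  # fixes in boxes outside the partition
        sel = labels == lab
        pts = fixes.loc[sel, ["x_m", "y_m"]].to_numpy(dtype=float)
        out.append(convex_hull_area(pts, label=str(lab), role=role))
    return out


def summarise_partition(partition, fixes: pd.DataFrame,
                        group_col: str = "group_id",
                        subset_cols: tuple[str, ...] = ()) -> dict:
    """Compare metastable clusters with observed social groups.

    ``fixes`` must carry coordinates and the group membership column;
    cluster labels come from the partition via box membership.  Returns a
    dict with the comparison table (one row per subset plus a pooled
    row: cluster/group counts and mean (SD) hull areas) and the per-hull
    summaries.
    """
    fixes = fixes.reset_index(drop=True)
    cluster_labels = partition.label_points(
        fixes[["x_m", "y_m"]].to_numpy(dtype=float))

    def one_subset(df: pd.DataFrame, labels: np.ndarray, name: str):
        clusters = _hull_family(df, labels, "cluster")
        groups = _hull_family(df, df[group_col].to_numpy(), "group")
        c_areas = np.array([h.area_km2 for h in clusters])
        g_areas = np.array([h.area_km2 for h in groups])
        row = {
            "subset": name,
            "n_groups": len(groups),
            "n_clusters": len(clusters),
            "group_area_mean": float(g_areas.mean()) if len(g_areas) else np.nan,
            "group_area_sd": float(g_areas.std(ddof=1)) if len(g_areas) > 1 else 0.0,
            "cluster_area_mean": float(c_areas.mean()) if len(c_areas) else np.nan,
            "cluster_area_sd": float(c_areas.std(ddof=1)) if len(c_areas) > 1 else 0.0,
            "n_fixes": len(df),
        }
        if len(groups) == 0:
            row.update(n_groups=0, n_clusters=len(clusters))
        return row, clusters, groups

    rows, all_clusters, all_groups = [], {}, {}
    if subset_cols:
        for key, df in fixes.groupby(list(subset_cols), sort=True):
            name = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
            labels = cluster_labels[df.index.to_numpy()]
            row, cl, gr = one_subset(df, labels, name)
            rows.append(row)
            all_clusters[name], all_groups[name] = cl, gr
    row, cl, gr = one_subset(fixes, cluster_labels, "Total")
    rows.append(row)
    all_clusters["Total"], all_groups["Total"] = cl, gr

    return {
        "table": pd.DataFrame(rows),
        "cluster_hulls": all_clusters,
        "group_hulls": all_groups,
        "cluster_labels": cluster_labels,
    }


def export_overlay(cluster_hulls: list[HullSummary],
                   group_hulls: list[HullSummary], path=None) -> dict:
    """Serialise hull families as a GeoJSON FeatureCollection.

    Planar (metre) coordinates; every feature carries its role
    ("cluster" or "group"), label, area and fix count, so plotting or
    GIS overlays can style the two families differently.
    """
    features = []
    for h in list(cluster_hulls) + list(group_hulls):
        if h.polygon is not None:
            geom = mapping(h.polygon)
        elif len(h.vertices) == 0:
            continue
        else:
            geom = {"type": "LineString" if len(h.vertices) > 1 else "Point",
                    "coordinates": (h.vertices.tolist() if len(h.vertices) > 1
                                    else h.vertices[0].tolist())}
        features.append({
            "type": "Feature",
            "geometry": geom,
            "properties": {
                "role": h.role,
                "label": h.label,
                "area_km2": h.area_km2,
                "n_fixes": h.n_fixes,
            },
        })
    collection = {"type": "FeatureCollection", "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(collection, fh)
    return collection


def load_overlay(path) -> list[HullSummary]:
    """Round-trip loader for :func:`export_overlay` files."""
    with open(path) as fh:
        collection = json.load(fh)
    out = []
    for feat in collection["features"]:
        geom = feat["geometry"]
        if geom["type"] == "Polygon":
            verts = np.asarray(geom["coordinates"][0][:-1], dtype=float)
        elif geom["type"] == "LineString":
            verts = np.asarray(geom["coordinates"], dtype=float)
        else:
            verts = np.asarray([geom["coordinates"]], dtype=float)
        p = feat["properties"]
        out.append(HullSummary(p["label"], p["role"], verts,
                               p["area_km2"], p["n_fixes"]))
    return out
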