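"""GeoJSON and CSV readers/writers for the pipeline's file interfaces."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .attribution import ServiceArea, TractRecord

__all__ = [
    "write_tracts_geojson", "read_tracts_geojson",
    "write_systems_geojson", "read_systems_geojson",
    "write_tests_csv", "read_tests_csv",
    "write_csv",
]


def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_tracts_geojson(tracts: list[TractRecord], path) -> None:
    features = []
    for t in tracts:
        props = {"tract_id": t.tract_id, "population": t.population}
        for name, cnt in t.subgroup_counts.items():
            props[f"subgroup_{name}"] = cnt
        features.append(
            {"type": "Feature", "geometry": mapping(t.polygon), "properties": props}
        )
    Path(path).write_text(json.dumps(_feature_collection(features), sort_keys=True))


def read_tracts_geojson(path) -> list[TractRecord]:
    fc = json.loads(Path(path).read_text())
    tracts = []
    for feat in fc["features"]:
        props = feat["properties"]
        subgroups = {
            k.removeprefix("subgroup_"): v
            for k, v in props.items()
            if k.startswith("subgroup_")
        }
        tracts.append(
            TractRecord(
                tract_id=str(props["tract_id"]),
                polygon=shape(feat["geometry"]),
                population=props["population"],
                subgroup_counts=subgroups,
            )
        )
    return tracts


def write_systems_geojson(systems: list[ServiceArea], path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": mapping(s.polygon),
            "properties": {"pwsid": s.pwsid, "reported_population": s.reported_population},
        }
        for s in systems
    ]
    Path(path).write_text(json.dumps(_feature_collection(features), sort_keys=True))


def read_systems_geojson(path) -> list[ServiceArea]:
    fc = json.loads(Path(path).read_text())
    return [
        ServiceArea(
            pwsid=str(f["properties"]["pwsid"]),
            polygon=shape(f["geometry"]),
            reported_population=f["properties"]["reported_population"],
        )
        for f in fc["features"]
    ]


def write_tests_csv(tests: pd.DataFrame, path) -> None:
    """Schema: pwsid,contaminant_id,sample_date,value,unit,nondetect.

    ``value`` is empty for non-detect rows; dates are ISO-8601.
    """
    out = tests.copy()
    out["value"] = out["value"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, index=False)


def read_tests_csv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"pwsid": str, "contaminant_id": str, "unit": str},
        parse_dates=["sample_date"],
    )
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    df["nondetect"] = df["nondetect"].astype(int)
    return df


def write_csv(df: pd.DataFrame, path, float_format: str = "%.12g") -> None:
    """Deterministic CSV output (fixed float formatting, no index)."""
    df = df.copy()
    for col in df.columns:  # normalize -0.0 and bool formatting
        if df[col].dtype == bool:
            df[col] = df[col].astype(int)
        elif np.issubdtype(df[col].dtype, np.floating):
            df[col] = df[col] + 0.0
    df.to_csv(path, index=False, float_format=float_format)
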