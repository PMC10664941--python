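"""Plain-text writers for pipeline artifacts (CSV, GeoJSON, ASCII grids)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .grid import GridLayer
from .synthetic_landscape import EATable


def _ea_polygon(eas: EATable, i: int) -> list:
    r0, r1, c0, c1 = eas.table.loc[i, ["row0", "row1", "col0", "col1"]]
    nr = eas.labels.shape[0]
    cs = eas.cell_size
    x0, x1 = c0 * cs, c1 * cs
    y0, y1 = (nr - r1) * cs, (nr - r0) * cs
    return [[[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]]


def write_ea_geojson(eas: EATable, path) -> None:
    features = []
    for i in range(eas.n_eas):
        props = eas.table.iloc[i].drop(
            ["row0", "row1", "col0", "col1"]).to_dict()
        props = {k: (v.item() if hasattr(v, "item") else v)
                 for k, v in props.items()}
        features.append({
            "type": "Feature",
            "geometry": {"type": "Polygon",
                         "coordinates": _ea_polygon(eas, i)},
            "properties": props,
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def write_facilities_geojson(facilities: pd.DataFrame, path) -> None:
    features = []
    for _, row in facilities.iterrows():
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(row["x"]), float(row["y"])]},
            "properties": {
                "facility_id": row["facility_id"],
                "ea_id": row["ea_id"],
                "treats_snakebite": bool(row["treats_snakebite"]),
            },
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))


def write_landscape(bundle: dict, out_dir) -> None:
    """Write a generate_landscape() bundle as text artifacts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, layer in bundle["rasters"].items():
        layer.write_ascii(out / f"{name}.asc")
    for s, layer in enumerate(bundle["species_layers"]):
        layer.write_ascii(out / f"suitability_{s:02d}.asc")
    bundle["occurrences"].to_csv(out / "occurrences.csv", index=False)
    eas: EATable = bundle["eas"]
    eas.table.to_csv(out / "eas.csv", index=False)
    write_ea_geojson(eas, out / "eas.geojson")
    GridLayer(eas.labels, cell_size=eas.cell_size).write_ascii(
        out / "ea_labels.asc")
    write_facilities_geojson(bundle["facilities"], out / "facilities.geojson")
    bundle["facilities"].to_csv(out / "facilities.csv", index=False)
    bundle["cases"].to_csv(out / "cases.csv", index=False)
    truth = bundle["truth"]
    pd.DataFrame({
        "ea_id": truth.archetype.index,
        "archetype": truth.archetype.to_numpy(),
        "expected_cases": truth.expected_cases.to_numpy(),
    }).to_csv(out / "truth.csv", index=False)


def read_eas(directory) -> EATable:
    directory = Path(directory)
    table = pd.read_csv(directory / "eas.csv")
    labels_layer = GridLayer.read_ascii(directory / "ea_labels.asc")
    return EATable(table=table,
                   labels=labels_layer.data.astype(int),
                   cell_size=labels_layer.cell_size)
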