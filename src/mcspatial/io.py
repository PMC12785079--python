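"""Readers and writers for detection tables, regions and morphometry.

Formats
-------
native detection table
    Tab-separated, UTF-8, one row per detection, columns
    ``sample_id, cell_id, x_um, y_um, nuc_major_um, nuc_minor_um, phenotype,
    group``. Coordinates in µm, image convention (origin top-left, y down).
qupath_export dialect
    Comma-separated whole-slide detection export: ``Image`` -> sample_id,
    ``Centroid X µm`` / ``Centroid Y µm`` -> coordinates, ``Class`` (or
    ``Classification``) -> phenotype. Marker names are mapped through the
    alias table (e.g. ``Tryptase`` -> MC, ``CD68`` -> CD68_M1); unknown
    labels map to ``other`` with a logged warning. Missing nuclear geometry
    falls back to the package default semi-axis (4 µm).
region
    GeoJSON with exactly one Polygon, coordinates in µm.
morphometry
    CSV columns ``sample_id, fibrosis, lumen_area_um2, diameter_um,
    cd138_count``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, shape

from .errors import FormatError
from .grading import MorphometryRecord
from .samples import (
    DETECTION_COLUMNS,
    PHENOTYPE_ALIASES,
    PHENOTYPES,
    TissueSample,
    canonical_group,
)

logger = logging.getLogger(__name__)

_DEFAULT_SEMIAXIS = 4.0  # µm, fallback when an export lacks nuclear geometry

_NATIVE_REQUIRED = ("sample_id", "cell_id", "x_um", "y_um", "nuc_major_um", "phenotype")
_QUPATH_CLASS_COLUMNS = ("Class", "Classification", "Name")


def _map_phenotypes(labels: pd.Series) -> pd.Series:
    mapped = labels.astype(str).str.strip().map(PHENOTYPE_ALIASES)
    unknown = mapped.isna()
    if unknown.any():
        examples = sorted(set(labels[unknown].astype(str)))[:5]
        logger.warning(
            "%d detections with unknown phenotype labels mapped to 'other' (e.g. %s)",
            int(unknown.sum()),
            examples,
        )
        mapped = mapped.fillna("other")
    return mapped


def _require_numeric(df: pd.DataFrame, column: str) -> np.ndarray:
    coerced = pd.to_numeric(df[column], errors="coerce")
    bad = coerced.isna() & df[column].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise FormatError(f"non-numeric value in column {column!r} at line {line}")
    return coerced.to_numpy(dtype=float)


def read_detections(path, dialect: str = "native") -> pd.DataFrame:
    """Read a detection table into the native column layout.

    Returns a DataFrame with the native columns; rows are never silently
    dropped — coerced phenotype labels are logged.
    """
    path = Path(path)
    if dialect == "native":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        missing = [c for c in _NATIVE_REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"native detection table missing column(s): {missing}")
        if "nuc_minor_um" not in df.columns:
            df["nuc_minor_um"] = np.nan
        if "group" not in df.columns:
            df["group"] = "control"
    elif dialect == "qupath_export":
        df_raw = pd.read_csv(path)
        class_col = next((c for c in _QUPATH_CLASS_COLUMNS if c in df_raw.columns), None)
        required = {"Centroid X µm": "x_um", "Centroid Y µm": "y_um"}
        missing = [c for c in required if c not in df_raw.columns]
        if missing:
            raise FormatError(f"qupath export missing column(s): {missing}")
        if class_col is None:
            raise FormatError(
                f"qupath export missing a class column (one of {_QUPATH_CLASS_COLUMNS})"
            )
        df = pd.DataFrame(
            {
                "sample_id": df_raw.get("Image", pd.Series(["sample"] * len(df_raw))).astype(str),
                "cell_id": df_raw.get("Object ID", pd.Series(range(len(df_raw)))),
                "x_um": df_raw["Centroid X µm"],
                "y_um": df_raw["Centroid Y µm"],
                "nuc_major_um": df_raw.get(
                    "Nucleus: Max diameter µm", pd.Series(np.nan, index=df_raw.index)
                )
                / 2.0,
                "nuc_minor_um": df_raw.get(
                    "Nucleus: Min diameter µm", pd.Series(np.nan, index=df_raw.index)
                )
                / 2.0,
                "phenotype": df_raw[class_col],
                "group": df_raw.get("group", pd.Series("control", index=df_raw.index)),
            }
        )
        n_fallback = int(df["nuc_major_um"].isna().sum())
        if n_fallback:
            logger.warning(
                "%d detections without nuclear geometry; semi-axis set to %.1f µm",
                n_fallback,
                _DEFAULT_SEMIAXIS,
            )
            df["nuc_major_um"] = df["nuc_major_um"].fillna(_DEFAULT_SEMIAXIS)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    for col in ("x_um", "y_um", "nuc_major_um", "nuc_minor_um"):
        df[col] = _require_numeric(df, col)
    if not np.isfinite(df[["x_um", "y_um"]].to_numpy()).all():
        raise FormatError("non-finite coordinates in detection table")
    if (df["nuc_major_um"] <= 0).any():
        raise FormatError("nuclear major semi-axes must be > 0")
    df["phenotype"] = _map_phenotypes(df["phenotype"])
    df["group"] = df["group"].map(canonical_group)
    return df[list(DETECTION_COLUMNS)].reset_index(drop=True)


def detections_to_samples(df: pd.DataFrame, region: Polygon | None = None) -> list[TissueSample]:
    """Group a detection table into TissueSamples (one per sample_id).

    With a region polygon, detections outside it are excluded with a logged
    count before the sample is built.
    """
    samples = []
    for sid, sub in df.groupby("sample_id", sort=True):
        sub = sub.reset_index(drop=True)
        if region is not None:
            inside = _points_in_polygon(sub[["x_um", "y_um"]].to_numpy(), region)
            n_out = int((~inside).sum())
            if n_out:
                logger.info("sample %s: %d detections outside region excluded", sid, n_out)
            sub = sub[inside].reset_index(drop=True)
        groups = sub["group"].unique()
        det = sub.drop(columns=["sample_id", "group"]).copy()
        det["phenotype"] = pd.Categorical(det["phenotype"], categories=list(PHENOTYPES))
        samples.append(
            TissueSample(
                sample_id=str(sid),
                group=str(groups[0]) if len(groups) else "control",
                detections=det,
                region=region,
            )
        )
    return samples


def _points_in_polygon(xy: np.ndarray, polygon: Polygon) -> np.ndarray:
    import shapely

    return shapely.covers(polygon, shapely.points(xy))


def load_samples(path, dialect: str = "native", region: Polygon | None = None) -> list[TissueSample]:
    """Convenience: read a detection table and build TissueSamples."""
    return detections_to_samples(read_detections(path, dialect=dialect), region=region)


def write_detections(samples: list[TissueSample], path) -> None:
    """Write a cohort as one native TSV (stable column order, UTF-8)."""
    frames = []
    for s in samples:
        df = s.detections.copy()
        df.insert(0, "sample_id", s.sample_id)
        df["group"] = s.group
        frames.append(df[list(DETECTION_COLUMNS)])
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(DETECTION_COLUMNS))
    )
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_region(path) -> Polygon:
    """Read a single GeoJSON Polygon (coordinates in µm)."""
    try:
        with open(path, encoding="utf-8") as fh:
            obj = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed GeoJSON: {exc}") from exc
    geoms = []
    if obj.get("type") == "FeatureCollection":
        geoms = [f.get("geometry", {}) for f in obj.get("features", [])]
    elif obj.get("type") == "Feature":
        geoms = [obj.get("geometry", {})]
    else:
        geoms = [obj]
    if len(geoms) != 1:
        raise FormatError(f"expected exactly one region feature, found {len(geoms)}")
    if geoms[0].get("type") != "Polygon":
        raise FormatError(f"region must be a Polygon, got {geoms[0].get('type')!r}")
    poly = shape(geoms[0])
    if not poly.is_valid or poly.area <= 0:
        raise FormatError("region polygon is invalid or degenerate")
    return poly


def read_morphometry(path) -> pd.DataFrame:
    """Read the morphometry CSV; returns one row per sample."""
    df = pd.read_csv(path)
    required = ("sample_id", "fibrosis", "lumen_area_um2", "diameter_um", "cd138_count")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"morphometry table missing column(s): {missing}")
    df["fibrosis"] = df["fibrosis"].map(
        lambda v: str(v).strip().lower() in ("1", "true", "yes")
    )
    return df


def morphometry_records(df: pd.DataFrame) -> dict:
    """sample_id -> MorphometryRecord from a morphometry table."""
    return {
        str(r.sample_id): MorphometryRecord(
            fibrosis=bool(r.fibrosis),
            lumen_area=float(r.lumen_area_um2),
            diameter=float(r.diameter_um),
            cd138_count=int(r.cd138_count),
        )
        for r in df.itertuples(index=False)
    }


def write_morphometry(records: dict, path) -> None:
    """Write sample_id -> MorphometryRecord as the morphometry CSV."""
    rows = [
        {
            "sample_id": sid,
            "fibrosis": rec.fibrosis,
            "lumen_area_um2": rec.lumen_area,
            "diameter_um": rec.diameter,
            "cd138_count": rec.cd138_count,
        }
        for sid, rec in records.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
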