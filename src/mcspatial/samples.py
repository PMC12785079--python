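"""Core containers: cell-detection tables and tissue samples.

Detections are held as a pandas DataFrame (one row per segmented cell) inside
a :class:`TissueSample`, which also carries the tissue region polygon and the
clinical group label. Coordinates are in µm, image convention (origin
top-left, y increasing downward).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

#: Controlled phenotype vocabulary. CD68_M1 = CD68+CD163- (type-1) macrophage;
#: CD163_M2 = CD163+ (type-2) macrophage; MC = tryptase+ mast cell.
PHENOTYPES = ("MC", "CD3", "CD8", "CD14", "CD68_M1", "CD163_M2", "other")

#: Clinical group labels: control, mild / moderate / severe chronic endometritis.
GROUPS = ("control", "MiCE", "MoCE", "SCE")

#: Accepted spellings for group labels on input.
GROUP_ALIASES = {
    "control": "control",
    "mild": "MiCE",
    "mice": "MiCE",
    "moderate": "MoCE",
    "moce": "MoCE",
    "severe": "SCE",
    "sce": "SCE",
}

#: Marker-name aliases mapped onto the controlled vocabulary. Unknown labels
#: map to "other" (with a logged warning) at the I/O boundary.
PHENOTYPE_ALIASES = {
    "MC": "MC",
    "Tryptase": "MC",
    "tryptase": "MC",
    "mast cell": "MC",
    "CD3": "CD3",
    "CD8": "CD8",
    "CD14": "CD14",
    "CD68": "CD68_M1",
    "CD68_M1": "CD68_M1",
    "M1": "CD68_M1",
    "CD68+CD163-": "CD68_M1",
    "CD163": "CD163_M2",
    "CD163_M2": "CD163_M2",
    "M2": "CD163_M2",
    "other": "other",
    "Other": "other",
}

#: Column order of the native detection table.
DETECTION_COLUMNS = (
    "sample_id",
    "cell_id",
    "x_um",
    "y_um",
    "nuc_major_um",
    "nuc_minor_um",
    "phenotype",
    "group",
)


def canonical_group(label: str) -> str:
    """Map a group spelling onto the canonical label set."""
    key = str(label).strip().lower()
    if key not in GROUP_ALIASES:
        raise ValueError(f"unknown group label: {label!r}")
    return GROUP_ALIASES[key]


def make_detections(
    x: np.ndarray,
    y: np.ndarray,
    phenotype,
    nuc_major: np.ndarray,
    nuc_minor: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assemble a validated detection table from coordinate arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if nuc_minor is None:
        nuc_minor = np.full(n, np.nan)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n, dtype=np.int64),
            "x_um": x,
            "y_um": y,
            "nuc_major_um": np.asarray(nuc_major, dtype=float),
            "nuc_minor_um": np.asarray(nuc_minor, dtype=float),
            "phenotype": pd.Categorical(phenotype, categories=list(PHENOTYPES)),
        }
    )
    if df["phenotype"].isna().any():
        bad = set(np.asarray(phenotype)[df["phenotype"].isna().to_numpy()])
        raise ValueError(f"phenotype labels outside vocabulary: {sorted(bad)}")
    if not np.isfinite(df[["x_um", "y_um"]].to_numpy()).all():
        raise ValueError("non-finite coordinates in detection table")
    if (df["nuc_major_um"].to_numpy() <= 0).any():
        raise ValueError("nuclear major semi-axes must be > 0")
    return df


@dataclass
class TissueSample:
    """One slide/region: detections plus region geometry and severity group."""

    sample_id: str
    group: str
    detections: pd.DataFrame
    region: Polygon = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.group = canonical_group(self.group)
        if self.region is None:
            # default region: bounding rectangle of the detections (or unit box)
            if len(self.detections):
                x = self.detections["x_um"]
                y = self.detections["y_um"]
                self.region = box(x.min(), y.min(), max(x.max(), x.min() + 1.0), max(y.max(), y.min() + 1.0))
            else:
                self.region = box(0.0, 0.0, 1.0, 1.0)
        if self.region.area <= 0:
            raise ValueError("region must have positive area")

    @property
    def area(self) -> float:
        """Region area in µm²."""
        return float(self.region.area)

    @property
    def n_cells(self) -> int:
        return int(len(self.detections))

    def coords(self, phenotype: str | None = None) -> np.ndarray:
        """(n, 2) centroid array, optionally restricted to one phenotype."""
        df = self.detections
        if phenotype is not None:
            df = df[df["phenotype"] == phenotype]
        return df[["x_um", "y_um"]].to_numpy(dtype=float)

    def phenotype_counts(self) -> pd.Series:
        return self.detections["phenotype"].value_counts()
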