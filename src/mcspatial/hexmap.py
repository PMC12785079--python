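"""Equal-area hexagonal density maps with accumulation-locus flagging.

The tissue region is tiled with hexagons of fixed area (default 8660 µm², so
side length s = sqrt(2A / (3*sqrt(3))) ≈ 57.735 µm), indexed by axial
coordinates (q, r). Each detection is assigned to exactly one hexagon by
fractional axial coordinates and cube rounding; per-phenotype counts are
conserved. Hexagons at or above a per-sample count quantile (over non-empty
hexagons) are flagged as accumulation loci, and two phenotypes' locus layers
combine into per-hexagon colocalization classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .errors import GridMismatchError
from .samples import TissueSample

DEFAULT_HEX_AREA = 8660.0  # µm²

_AXIAL_NEIGHBORS = ((1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1))


def side_from_area(hex_area: float) -> float:
    """Hexagon side length for a given area: s = sqrt(2A / (3*sqrt(3)))."""
    if hex_area <= 0:
        raise ValueError("hex_area must be > 0")
    return math.sqrt(2.0 * hex_area / (3.0 * math.sqrt(3.0)))


@dataclass
class HexGrid:
    """Axial-indexed hexagonal tiling covering a region."""

    hex_area: float
    orientation: str  # pointy | flat
    origin: tuple[float, float]
    indices: np.ndarray = field(repr=False)  # (n, 2) int array of (q, r)

    def __post_init__(self):
        if self.orientation not in ("pointy", "flat"):
            raise ValueError(f"unknown orientation: {self.orientation!r}")
        self.side = side_from_area(self.hex_area)
        self._index_set = {tuple(qr) for qr in np.asarray(self.indices)}

    def __contains__(self, qr) -> bool:
        return tuple(qr) in self._index_set

    def __len__(self) -> int:
        return len(self.indices)

    # ---- geometry ----------------------------------------------------------
    def centers(self, indices: np.ndarray | None = None) -> np.ndarray:
        qr = np.asarray(self.indices if indices is None else indices, dtype=float)
        q, r = qr[:, 0], qr[:, 1]
        s = self.side
        ox, oy = self.origin
        if self.orientation == "pointy":
            x = s * math.sqrt(3.0) * (q + r / 2.0)
            y = s * 1.5 * r
        else:
            x = s * 1.5 * q
            y = s * math.sqrt(3.0) * (r + q / 2.0)
        return np.column_stack([x + ox, y + oy])

    def vertices(self, q: int, r: int) -> np.ndarray:
        """(6, 2) vertex array of one hexagon."""
        cx, cy = self.centers(np.array([[q, r]]))[0]
        start = math.pi / 6.0 if self.orientation == "pointy" else 0.0
        ang = start + np.arange(6) * (math.pi / 3.0)
        return np.column_stack([cx + self.side * np.cos(ang), cy + self.side * np.sin(ang)])

    def polygon(self, q: int, r: int) -> Polygon:
        return Polygon(self.vertices(q, r))

    def to_axial(self, xy: np.ndarray) -> np.ndarray:
        """Assign points to hexagons: fractional axial coords + cube rounding."""
        xy = np.asarray(xy, dtype=float)
        x = xy[:, 0] - self.origin[0]
        y = xy[:, 1] - self.origin[1]
        s = self.side
        if self.orientation == "pointy":
            qf = (math.sqrt(3.0) / 3.0 * x - y / 3.0) / s
            rf = (2.0 / 3.0 * y) / s
        else:
            qf = (2.0 / 3.0 * x) / s
            rf = (-x / 3.0 + math.sqrt(3.0) / 3.0 * y) / s
        return _cube_round(qf, rf)


def _cube_round(qf: np.ndarray, rf: np.ndarray) -> np.ndarray:
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q[fix_q] = -r[fix_q] - s[fix_q]
    r[fix_r] = -q[fix_r] - s[fix_r]
    return np.column_stack([q, r]).astype(np.int64)


def build_grid(
    region: Polygon,
    hex_area: float = DEFAULT_HEX_AREA,
    orientation: str = "pointy",
    origin: tuple[float, float] | None = None,
) -> HexGrid:
    """Tile the region's bounding box; retain hexagons intersecting the region."""
    if region.area <= 0:
        raise ValueError("degenerate region")
    minx, miny, maxx, maxy = region.bounds
    if origin is None:
        origin = (minx, miny)
    s = side_from_area(hex_area)
    probe = HexGrid(hex_area=hex_area, orientation=orientation, origin=origin,
                    indices=np.empty((0, 2), dtype=np.int64))
    # candidate axial range from the bbox corners, padded by one hexagon
    corners = np.array([[minx - s, miny - s], [maxx + s, miny - s],
                        [minx - s, maxy + s], [maxx + s, maxy + s]])
    qr = probe.to_axial(corners)
    q_rng = np.arange(qr[:, 0].min() - 1, qr[:, 0].max() + 2)
    r_rng = np.arange(qr[:, 1].min() - 1, qr[:, 1].max() + 2)
    qq, rr = np.meshgrid(q_rng, r_rng, indexing="ij")
    cand = np.column_stack([qq.ravel(), rr.ravel()]).astype(np.int64)
    centers = HexGrid(hex_area=hex_area, orientation=orientation, origin=origin,
                      indices=cand).centers()
    # coarse prefilter: hexagon ⊂ disk(center, s)
    near = (
        (centers[:, 0] >= minx - s) & (centers[:, 0] <= maxx + s)
        & (centers[:, 1] >= miny - s) & (centers[:, 1] <= maxy + s)
    )
    cand, centers = cand[near], centers[near]
    start = math.pi / 6.0 if orientation == "pointy" else 0.0
    ang = start + np.arange(6) * (math.pi / 3.0)
    verts = centers[:, None, :] + s * np.stack(
        [np.cos(ang), np.sin(ang)], axis=-1
    )[None, :, :]
    polys = shapely.polygons(verts)
    keep = shapely.intersects(polys, region)
    return HexGrid(hex_area=hex_area, orientation=orientation, origin=origin,
                   indices=cand[keep])


@dataclass
class HexDensityMap:
    """Per-hexagon, per-phenotype counts on a HexGrid."""

    grid: HexGrid
    counts: pd.DataFrame  # MultiIndex (q, r) rows × phenotype columns
    overflow: dict  # phenotype -> count of detections outside the grid


def assign_counts(
    sample: TissueSample,
    grid: HexGrid,
    phenotypes: list[str] | None = None,
) -> HexDensityMap:
    """Count detections per hexagon and phenotype.

    Every detection is assigned to exactly one hexagon; detections mapping
    outside the grid are tallied in a reported overflow bin, never dropped.
    """
    df = sample.detections
    if phenotypes is None:
        phenotypes = [p for p in df["phenotype"].cat.categories if (df["phenotype"] == p).any()]
    index = pd.MultiIndex.from_arrays(
        [grid.indices[:, 0], grid.indices[:, 1]], names=["hex_q", "hex_r"]
    )
    counts = pd.DataFrame(0, index=index, columns=list(phenotypes), dtype=np.int64)
    overflow: dict = {}
    for pheno in phenotypes:
        xy = sample.coords(pheno)
        if len(xy) == 0:
            overflow[pheno] = 0
            continue
        qr = grid.to_axial(xy)
        keys = pd.MultiIndex.from_arrays([qr[:, 0], qr[:, 1]])
        tab = pd.Series(1, index=keys).groupby(level=[0, 1]).sum()
        tab.index.names = ["hex_q", "hex_r"]
        in_grid = tab.index.isin(counts.index)
        counts.loc[tab.index[in_grid], pheno] = tab[in_grid].to_numpy()
        overflow[pheno] = int(tab[~in_grid].sum())
    return HexDensityMap(grid=grid, counts=counts, overflow=overflow)


@dataclass
class Locus:
    """A connected component of flagged hexagons."""

    hexes: list
    area_um2: float


@dataclass
class LocusFlags:
    """Locus flags for one phenotype layer plus the merged connected loci."""

    phenotype: str
    flags: pd.Series  # bool, indexed like the map's counts
    threshold: float
    loci: list


def flag_loci(density_map: HexDensityMap, phenotype: str, quantile: float = 0.90) -> LocusFlags:
    """Flag accumulation loci: hexagons at/above the count quantile.

    The quantile is taken over non-empty hexagons only; adjacent flagged
    hexagons merge into connected loci with area = n_hex × hex_area.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    counts = density_map.counts[phenotype]
    nonempty = counts[counts > 0]
    if nonempty.empty:
        flags = pd.Series(False, index=counts.index)
        return LocusFlags(phenotype=phenotype, flags=flags, threshold=np.nan, loci=[])
    threshold = float(np.quantile(nonempty.to_numpy(), quantile))
    flags = (counts >= threshold) & (counts > 0)
    loci = _connected_loci(flags, density_map.grid.hex_area)
    return LocusFlags(phenotype=phenotype, flags=flags, threshold=threshold, loci=loci)


def _connected_loci(flags: pd.Series, hex_area: float) -> list:
    flagged = {qr for qr, f in flags.items() if f}
    loci = []
    seen: set = set()
    for start in sorted(flagged):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            q, r = stack.pop()
            comp.append((q, r))
            for dq, dr in _AXIAL_NEIGHBORS:
                nb = (q + dq, r + dr)
                if nb in flagged and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        loci.append(Locus(hexes=sorted(comp), area_um2=len(comp) * hex_area))
    return loci


def colocalization_classes(
    flags_a: LocusFlags, flags_b: LocusFlags
) -> pd.DataFrame:
    """Per-hexagon colocalization class from two locus-flag layers.

    Labels: ``both`` (loci of A and B overlap), ``A_only``, ``B_only``,
    ``neither``. Raises :class:`GridMismatchError` when the layers index
    different grids.
    """
    if not flags_a.flags.index.equals(flags_b.flags.index):
        raise GridMismatchError("locus layers live on different grids")
    a = flags_a.flags
    b = flags_b.flags
    label = np.where(a & b, "both", np.where(a, "A_only", np.where(b, "B_only", "neither")))
    return pd.DataFrame({"class": label}, index=a.index)


def colocalization_summary(classes: pd.DataFrame, hex_area: float) -> pd.DataFrame:
    """Hexagon counts and total areas per colocalization class."""
    counts = classes["class"].value_counts().reindex(
        ["A_only", "B_only", "both", "neither"], fill_value=0
    )
    return pd.DataFrame({"n_hex": counts, "area_um2": counts * hex_area})


def map_table(density_map: HexDensityMap, flags: dict | None = None) -> pd.DataFrame:
    """Long-format export: one row per hexagon and phenotype."""
    centers = density_map.grid.centers()
    center_lookup = pd.DataFrame(
        centers, index=density_map.counts.index, columns=["center_x_um", "center_y_um"]
    )
    rows = []
    for pheno in density_map.counts.columns:
        sub = pd.DataFrame(
            {
                "phenotype": pheno,
                "count": density_map.counts[pheno],
                "locus_flag": flags[pheno].flags if flags and pheno in flags else False,
            },
            index=density_map.counts.index,
        )
        rows.append(sub.join(center_lookup))
    out = pd.concat(rows).reset_index()
    return out[
        ["hex_q", "hex_r", "center_x_um", "center_y_um", "phenotype", "count", "locus_flag"]
    ]
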