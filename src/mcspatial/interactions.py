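"""Nearest-partner distances and juxtacrine/paracrine band classification.

For every source-phenotype cell (typically an MC) the minimum Euclidean
centroid distance to the target phenotype is computed, then classified into
interaction bands: < 10 µm juxtacrine (contacting), 10–20 µm paracrine,
> 20 µm non-interacting. The profile reports band counts and the percentage
of the source population in each band; "colocalized" means juxtacrine or
paracrine combined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptySourceError
from .samples import TissueSample

logger = logging.getLogger(__name__)


@dataclass
class DistanceBands:
    """Interaction band edges.

    In ``fixed`` mode the contact cap is ``contact_max``; in ``nuclear_sum``
    mode a pair is contacting when its centroid distance is below the sum of
    the two nuclear major semi-axes (capped at ``contact_max``), reflecting
    the definition of contact via nuclear geometry.
    """

    contact_max: float = 10.0  # µm
    paracrine_max: float = 20.0  # µm
    mode: str = "fixed"  # fixed | nuclear_sum

    def __post_init__(self):
        if not 0 < self.contact_max < self.paracrine_max:
            raise ValueError("need 0 < contact_max < paracrine_max")
        if self.mode not in ("fixed", "nuclear_sum"):
            raise ValueError(f"unknown band mode: {self.mode!r}")


@dataclass
class InteractionProfile:
    """Distance-band profile of one source->target phenotype pair."""

    source_phenotype: str
    target_phenotype: str
    n_source: int
    n_juxtacrine: int
    n_paracrine: int
    n_noninteracting: int
    distances: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def pct_juxtacrine(self) -> float:
        return 100.0 * self.n_juxtacrine / self.n_source

    @property
    def pct_paracrine(self) -> float:
        return 100.0 * self.n_paracrine / self.n_source

    @property
    def pct_colocalized(self) -> float:
        return self.pct_juxtacrine + self.pct_paracrine


def nearest_partner(
    sample: TissueSample, source: str, target: str
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-target distance and target row index for every source cell.

    Self-pairs are excluded when source == target. Returns (distances,
    indices); distances are +inf (index -1) when the sample has no target
    cells. Raises :class:`EmptySourceError` when there are no source cells —
    a distinct condition from an empty target.
    """
    src_xy = sample.coords(source)
    if len(src_xy) == 0:
        raise EmptySourceError(f"sample {sample.sample_id} has no {source} cells")
    tgt_df = sample.detections[sample.detections["phenotype"] == target]
    tgt_xy = tgt_df[["x_um", "y_um"]].to_numpy(dtype=float)
    if len(tgt_xy) == 0 or (source == target and len(tgt_xy) < 2):
        return np.full(len(src_xy), np.inf), np.full(len(src_xy), -1, dtype=np.int64)
    tree = cKDTree(tgt_xy)
    if source == target:
        d, i = tree.query(src_xy, k=2)
        # positions coincide row-for-row; drop the self match (column 0)
        dist, idx = d[:, 1], i[:, 1]
    else:
        dist, idx = tree.query(src_xy, k=1)
    return np.asarray(dist, dtype=float), tgt_df.index.to_numpy()[idx]


def nearest_partner_distances(sample: TissueSample, source: str, target: str) -> np.ndarray:
    """Minimum Euclidean centroid distance to ``target`` per ``source`` cell."""
    return nearest_partner(sample, source, target)[0]


def classify_distances(
    distances: np.ndarray,
    bands: DistanceBands = DistanceBands(),
    source_semiaxes: np.ndarray | None = None,
    target_semiaxes: np.ndarray | None = None,
) -> tuple[int, int, int]:
    """Band counts (juxtacrine, paracrine, non-interacting) for one profile.

    Fixed mode: d < contact_max -> juxtacrine; contact_max <= d <=
    paracrine_max -> paracrine; d > paracrine_max (including +inf) ->
    non-interacting. Nuclear-sum mode replaces the contact cap per pair with
    min(a_source + a_target, contact_max).
    """
    d = np.asarray(distances, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if bands.mode == "nuclear_sum":
        if source_semiaxes is None or target_semiaxes is None:
            raise ValueError("nuclear_sum mode requires semi-axes of the realized pairs")
        cap = np.minimum(
            np.asarray(source_semiaxes, float) + np.asarray(target_semiaxes, float),
            bands.contact_max,
        )
    else:
        cap = bands.contact_max
    juxta = d < cap
    para = ~juxta & (d <= bands.paracrine_max)
    n_j = int(juxta.sum())
    n_p = int(para.sum())
    return n_j, n_p, len(d) - n_j - n_p


def interaction_profile(
    sample: TissueSample,
    source: str,
    target: str,
    bands: DistanceBands = DistanceBands(),
) -> InteractionProfile:
    """Nearest-partner distances classified into an InteractionProfile."""
    dist, tgt_idx = nearest_partner(sample, source, target)
    if bands.mode == "nuclear_sum":
        src = sample.detections[sample.detections["phenotype"] == source]
        a_src = src["nuc_major_um"].to_numpy(dtype=float)
        a_tgt = np.zeros(len(dist))
        valid = tgt_idx >= 0
        if valid.any():
            a_tgt[valid] = sample.detections.loc[tgt_idx[valid], "nuc_major_um"].to_numpy()
        n_j, n_p, n_n = classify_distances(dist, bands, a_src, a_tgt)
    else:
        n_j, n_p, n_n = classify_distances(dist, bands)
    return InteractionProfile(
        source_phenotype=source,
        target_phenotype=target,
        n_source=len(dist),
        n_juxtacrine=n_j,
        n_paracrine=n_p,
        n_noninteracting=n_n,
        distances=dist,
    )


def profiles_table(
    samples: list[TissueSample],
    source: str,
    targets: list[str],
    bands: DistanceBands = DistanceBands(),
) -> pd.DataFrame:
    """Tidy per-sample, per-target profile table.

    Samples with zero source cells are skipped with a logged warning.
    """
    rows = []
    for s in samples:
        for t in targets:
            try:
                p = interaction_profile(s, source, t, bands)
            except EmptySourceError:
                logger.warning("sample %s: no %s cells; profile skipped", s.sample_id, source)
                continue
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "group": s.group,
                    "source": source,
                    "target": t,
                    "n_source": p.n_source,
                    "n_juxta": p.n_juxtacrine,
                    "n_para": p.n_paracrine,
                    "n_none": p.n_noninteracting,
                    "pct_juxta": p.pct_juxtacrine,
                    "pct_para": p.pct_paracrine,
                    "pct_coloc": p.pct_colocalized,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "group", "source", "target", "n_source",
            "n_juxta", "n_para", "n_none", "pct_juxta", "pct_para", "pct_coloc",
        ],
    )
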