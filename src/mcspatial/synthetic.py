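"""Synthetic tissue-sample generator.

Emulates detection tables from multiplex-stained endometrial sections:

* a homogeneous Poisson background of "other" stromal/epithelial cells;
* mast cells (MCs) from a Thomas (Neyman-Scott) cluster process, reproducing
  the locus-like accumulation of MCs seen in inflamed endometrium;
* partner immune phenotypes (CD8, CD14, CD68_M1, CD163_M2, CD3) as uniform
  background plus, for a configured fraction of MCs, one partner placed in
  the juxtacrine ([1, 10) µm) or paracrine ([10, 20] µm) annulus around the MC.

Coupling semantics
------------------
The coupling targets ``(p_juxta, p_para)`` are the band fractions the
downstream nearest-partner analysis should *measure*. Uniform background
partners already land within the interaction bands of some MCs by chance, so
the generator first scores each MC against the background, then tops up only
MCs without a chance partner, scaled by the realized chance fractions, and
rejection-samples placed partners away (>20 µm) from every other MC so one
MC's partner cannot silently colocalize a second MC. The measured band
fractions are then unbiased binomial estimates of the targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import box

from .errors import CouplingInfeasibleError
from .grading import MorphometryRecord
from .samples import GROUP_ALIASES, TissueSample, canonical_group, make_detections

# Interaction band edges used for coupled-partner placement (µm).
JUXTA_MAX = 10.0
PARA_MAX = 20.0
MIN_PARTNER_OFFSET = 1.0  # coincident centroids are non-physical

_PLACEMENT_MAX_TRIES = 40


@dataclass
class SimulationConfig:
    """Parameters of one synthetic tissue sample.

    Fractions are of the total expected cell count; coupling maps partner
    phenotype -> (p_juxta, p_para), the target fractions of MCs whose nearest
    partner of that phenotype falls in the juxtacrine / paracrine band.
    """

    region_width: float = 3200.0  # µm
    region_height: float = 3200.0  # µm
    total_cell_density: float = 3000.0  # cells per mm²
    mc_fraction: float = 0.00206
    cluster_parent_intensity: float | None = None  # parents per mm²; derived if None
    cluster_mean_offspring: float = 5.0
    cluster_radius_sd: float = 60.0  # µm
    partner_fractions: dict = field(default_factory=dict)  # phenotype -> fraction
    coupling: dict = field(default_factory=dict)  # phenotype -> (p_juxta, p_para)
    nuclear_semiaxis_mean: float = 4.0  # µm
    nuclear_semiaxis_sd: float = 1.0  # µm
    seed: int = 0

    def validate(self) -> None:
        if self.region_width <= 0 or self.region_height <= 0:
            raise ValueError("region dimensions must be positive")
        if self.total_cell_density < 0:
            raise ValueError("total_cell_density must be >= 0")
        if not 0.0 <= self.mc_fraction <= 1.0:
            raise ValueError("mc_fraction must lie in [0, 1]")
        if self.cluster_mean_offspring < 0:
            raise ValueError("cluster_mean_offspring must be >= 0")
        for pheno, f in self.partner_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"partner fraction for {pheno} outside [0, 1]")
        total = self.mc_fraction + sum(self.partner_fractions.values())
        if total > 1.0 + 1e-12:
            raise ValueError("mc_fraction + partner fractions exceed 1")
        for pheno, (pj, pp) in self.coupling.items():
            if pj < 0 or pp < 0 or pj + pp > 1.0 + 1e-12:
                raise ValueError(f"coupling for {pheno}: need p_juxta, p_para >= 0 and sum <= 1")
            if pheno not in self.partner_fractions:
                raise ValueError(f"coupling given for {pheno} but no partner fraction")
        if self.nuclear_semiaxis_mean <= 0 or self.nuclear_semiaxis_sd < 0:
            raise ValueError("nuclear semi-axis parameters invalid")

    # ---- derived quantities -------------------------------------------------
    @property
    def area_um2(self) -> float:
        return self.region_width * self.region_height

    @property
    def density_per_um2(self) -> float:
        return self.total_cell_density / 1e6

    @property
    def expected_total_cells(self) -> float:
        return self.density_per_um2 * self.area_um2


@dataclass
class CohortDesign:
    """Group sizes and per-group simulation presets for a whole cohort."""

    group_sizes: dict  # group label -> n samples
    configs: dict  # group label -> SimulationConfig

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            canonical_group(g)
            if n < 1:
                raise ValueError(f"group size for {g} must be >= 1")
            if g not in self.configs:
                raise ValueError(f"no SimulationConfig for group {g}")
        for cfg in self.configs.values():
            cfg.validate()


# ---------------------------------------------------------------------------
# point-process primitives
# ---------------------------------------------------------------------------

def _uniform_points(rng: np.random.Generator, n: int, w: float, h: float) -> np.ndarray:
    return rng.uniform((0.0, 0.0), (w, h), size=(n, 2)) if n else np.empty((0, 2))


def _thomas_points(
    rng: np.random.Generator,
    expected: float,
    w: float,
    h: float,
    mean_offspring: float,
    radius_sd: float,
    parent_intensity_um2: float | None = None,
) -> np.ndarray:
    """Thomas cluster process restricted to [0,w]x[0,h], expected count given.

    Parents live on a window extended by 4 sd so edge clusters contribute;
    offspring scatter isotropically N(0, radius_sd²) around their parent.
    """
    if expected <= 0 or mean_offspring <= 0:
        return np.empty((0, 2))
    margin = 4.0 * radius_sd
    w_ext, h_ext = w + 2 * margin, h + 2 * margin
    kappa = (
        parent_intensity_um2
        if parent_intensity_um2 is not None
        else expected / (mean_offspring * w * h)
    )
    n_parents = rng.poisson(kappa * w_ext * h_ext)
    if n_parents == 0:
        return np.empty((0, 2))
    parents = rng.uniform((-margin, -margin), (w + margin, h + margin), size=(n_parents, 2))
    n_off = rng.poisson(mean_offspring, size=n_parents)
    pts = np.repeat(parents, n_off, axis=0)
    pts = pts + rng.normal(0.0, radius_sd, size=pts.shape)
    inside = (pts[:, 0] >= 0) & (pts[:, 0] <= w) & (pts[:, 1] >= 0) & (pts[:, 1] <= h)
    return pts[inside]


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal(mean, sd) truncated to > 0 by resampling."""
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def _chance_within(lam: float, radius: float) -> float:
    """P(nearest point of a Poisson process of intensity lam within radius)."""
    return 1.0 - math.exp(-lam * math.pi * radius * radius)


def _annulus_offsets(rng: np.random.Generator, n: int, r1: float, r2: float) -> np.ndarray:
    u = rng.random(n)
    r = np.sqrt(u * (r2 * r2 - r1 * r1) + r1 * r1)
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


# ---------------------------------------------------------------------------
# coupled-partner realization
# ---------------------------------------------------------------------------

def _realize_partner_phenotype(
    rng: np.random.Generator,
    mc_xy: np.ndarray,
    mc_tree: cKDTree | None,
    fraction: float,
    coupling: tuple[float, float],
    cfg: SimulationConfig,
) -> np.ndarray:
    """Generate one partner phenotype's positions (background + coupled)."""
    w, h = cfg.region_width, cfg.region_height
    area = cfg.area_um2
    n_mc = len(mc_xy)
    p_juxta, p_para = coupling
    c = p_juxta + p_para
    expected_partners = fraction * cfg.expected_total_cells
    expected_mc = cfg.mc_fraction * cfg.expected_total_cells

    if c > 0 and c * expected_mc > expected_partners + 1e-9:
        raise CouplingInfeasibleError(
            f"coupling target {c:.3f} x {expected_mc:.0f} expected MCs exceeds the "
            f"partner budget ({expected_partners:.0f} cells)"
        )

    # Background intensity: total budget minus the expected coupled count,
    # solved by fixed-point iteration (the coupled count depends on chance
    # colocalization, which depends on the background intensity).
    lam_b = fraction * cfg.density_per_um2
    if c > 0 and expected_mc > 0:
        for _ in range(3):
            q20 = _chance_within(lam_b, PARA_MAX)
            coupled_density = max(0.0, c - q20) * expected_mc / area
            lam_b = max(0.0, fraction * cfg.density_per_um2 - coupled_density)
        if _chance_within(lam_b, PARA_MAX) >= c:
            raise CouplingInfeasibleError(
                f"chance colocalization at partner density {fraction:.4f} already "
                f"exceeds the coupling target {c:.4f}"
            )

    background = _uniform_points(rng, rng.poisson(lam_b * area), w, h)
    if c <= 0 or n_mc == 0:
        return background

    # Chance band of every MC against the background alone.
    if len(background):
        d0, _ = cKDTree(background).query(mc_xy, k=1)
    else:
        d0 = np.full(n_mc, np.inf)
    chance_juxta = d0 < JUXTA_MAX
    chance_para = (d0 >= JUXTA_MAX) & (d0 <= PARA_MAX)
    free = ~(chance_juxta | chance_para)

    # Per-MC independent thinning against the analytic chance probabilities
    # (realized per-sample fractions would bias small samples through the
    # clipping at zero): each MC ends colocalized with probability exactly
    # p_juxta + p_para, in the right band whenever the targets allow it.
    q10 = _chance_within(lam_b, JUXTA_MAX)
    q20 = _chance_within(lam_b, PARA_MAX)
    q_band = q20 - q10  # chance paracrine probability
    alpha_j = (p_juxta - q10) / (1.0 - q20)
    alpha_p = (p_para - q_band) / (1.0 - q20)
    beta = 0.0  # promotion of chance-paracrine MCs to placed juxtacrine
    if alpha_p < 0.0 and q_band > 0:
        # chance alone already exceeds the paracrine target: promote the
        # surplus to juxtacrine (a placed partner < 10 µm overrides d0 >= 10)
        beta = min(1.0, (q_band - p_para) / q_band)
        alpha_j = (p_juxta - q10 - q_band * beta) / (1.0 - q20)
        alpha_p = 0.0
    if alpha_j < 0.0:
        # chance juxtacrine exceeds the juxtacrine target; keep the combined
        # fraction on target and let the band split absorb the excess
        alpha_p = max(0.0, (c - q20) / (1.0 - q20))
        alpha_j = 0.0
    alpha_j = min(alpha_j, 1.0)
    alpha_p = min(alpha_p, 1.0 - alpha_j)

    couple_band = np.zeros(n_mc, dtype=np.int8)  # 0 none, 1 juxta, 2 para
    u = rng.random(n_mc)
    couple_band[free & (u < alpha_j)] = 1
    couple_band[free & (u >= alpha_j) & (u < alpha_j + alpha_p)] = 2
    if beta > 0.0:
        couple_band[chance_para & (rng.random(n_mc) < beta)] = 1

    placed = []
    for band, (r1, r2) in ((1, (MIN_PARTNER_OFFSET, JUXTA_MAX - 1e-9)), (2, (JUXTA_MAX, PARA_MAX))):
        idx = np.flatnonzero(couple_band == band)
        for i in idx:
            pos = None
            for _ in range(_PLACEMENT_MAX_TRIES):
                cand = mc_xy[i] + _annulus_offsets(rng, 1, r1, r2)[0]
                if not (0 <= cand[0] <= w and 0 <= cand[1] <= h):
                    continue
                if mc_tree is not None and n_mc > 1:
                    dd, ii = mc_tree.query(cand, k=2)
                    d_other = dd[1] if ii[0] == i else dd[0]
                    if d_other <= PARA_MAX:
                        continue
                pos = cand
                break
            if pos is None:  # crowded neighborhood: accept the in-region draw
                off = _annulus_offsets(rng, 1, r1, r2)[0]
                pos = np.clip(mc_xy[i] + off, (0.0, 0.0), (w, h))
            placed.append(pos)
    placed_arr = np.asarray(placed) if placed else np.empty((0, 2))
    return np.vstack([background, placed_arr])


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate_sample(
    config: SimulationConfig,
    seed: int | None = None,
    sample_id: str = "sample",
    group: str = "control",
) -> TissueSample:
    """Generate one synthetic tissue sample.

    MCs follow a Thomas cluster process with expected count
    ``mc_fraction x expected total``; partner phenotypes combine uniform
    background with distance-coupled placement (module docstring); remaining
    cells are a homogeneous Poisson "other" background. Deterministic for a
    fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    w, h = config.region_width, config.region_height

    mc_xy = _thomas_points(
        rng,
        expected=config.mc_fraction * config.expected_total_cells,
        w=w,
        h=h,
        mean_offspring=config.cluster_mean_offspring,
        radius_sd=config.cluster_radius_sd,
        parent_intensity_um2=(
            config.cluster_parent_intensity / 1e6
            if config.cluster_parent_intensity is not None
            else None
        ),
    )
    mc_tree = cKDTree(mc_xy) if len(mc_xy) else None

    xs, labels = [mc_xy], ["MC"] * len(mc_xy)
    for pheno in sorted(config.partner_fractions):
        pts = _realize_partner_phenotype(
            rng,
            mc_xy,
            mc_tree,
            config.partner_fractions[pheno],
            tuple(config.coupling.get(pheno, (0.0, 0.0))),
            config,
        )
        xs.append(pts)
        labels.extend([pheno] * len(pts))

    resid = 1.0 - config.mc_fraction - sum(config.partner_fractions.values())
    n_other = rng.poisson(resid * config.expected_total_cells) if resid > 0 else 0
    other = _uniform_points(rng, n_other, w, h)
    xs.append(other)
    labels.extend(["other"] * len(other))

    xy = np.vstack(xs)
    n = len(xy)
    major = _positive_normal(rng, config.nuclear_semiaxis_mean, config.nuclear_semiaxis_sd, n)
    minor = major * rng.uniform(0.55, 0.95, size=n)
    detections = make_detections(xy[:, 0], xy[:, 1], labels, major, minor)
    return TissueSample(
        sample_id=sample_id,
        group=group,
        detections=detections,
        region=box(0.0, 0.0, w, h),
    )


def simulate_cohort(design: CohortDesign, seed: int = 0) -> list[TissueSample]:
    """Generate a full cohort; per-sample seeds derive from the master seed."""
    design.validate()
    samples: list[TissueSample] = []
    for g in design.group_sizes:
        n = design.group_sizes[g]
        cfg = design.configs[g]
        glabel = canonical_group(g)
        for i in range(n):
            child = np.random.SeedSequence([seed, _group_tag(g), i])
            samples.append(
                simulate_sample(
                    cfg,
                    seed=int(child.generate_state(1)[0]),
                    sample_id=f"{glabel}_{i + 1:02d}",
                    group=glabel,
                )
            )
    return samples


def _group_tag(group: str) -> int:
    """Stable small integer per group label, for seed derivation."""
    order = list(GROUP_ALIASES)
    key = str(group).strip().lower()
    return order.index(key) if key in order else (hash(key) % 997)


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

#: Per-grade morphometric ranges (fibrosis, lumen area µm², arteriolar
#: diameter µm, CD138+ plasma-cell count).
_MORPHO_RANGES = {
    "mild": dict(fibrosis=False, lumen=(150, 449), diameter=(10.0, 19.9), cd138=(0, 1)),
    "moderate": dict(fibrosis=True, lumen=(100, 149), diameter=(8.0, 9.9), cd138=(2, 3)),
    "severe": dict(fibrosis=True, lumen=(20, 99), diameter=(3.0, 7.9), cd138=(4, 12)),
}


def simulate_morphometry(grade: str, seed: int | None = None, rng=None) -> MorphometryRecord:
    """Draw a morphometry record uniformly within one severity grade's ranges."""
    if grade not in _MORPHO_RANGES:
        raise ValueError(f"unknown grade: {grade!r} (expected mild/moderate/severe)")
    if rng is None:
        rng = np.random.default_rng(seed)
    r = _MORPHO_RANGES[grade]
    lumen = int(rng.integers(r["lumen"][0], r["lumen"][1] + 1))
    # diameters are reported at 0.1 µm resolution
    lo, hi = (round(v * 10) for v in r["diameter"])
    diameter = int(rng.integers(lo, hi + 1)) / 10.0
    cd138 = int(rng.integers(r["cd138"][0], r["cd138"][1] + 1))
    return MorphometryRecord(
        fibrosis=r["fibrosis"],
        lumen_area=float(lumen),
        diameter=diameter,
        cd138_count=cd138,
    )
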