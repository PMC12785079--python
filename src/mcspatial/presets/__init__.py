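"""Severity-group simulation presets, shipped as a plain-text config file."""

from __future__ import annotations

import configparser
from importlib import resources

from ..synthetic import CohortDesign, SimulationConfig

PRESET_GROUPS = ("control", "mild", "moderate", "severe")

_COLOC_KEYS = {
    "CD8": "coloc_cd8_pct",
    "CD14": "coloc_cd14_pct",
    "CD68_M1": "coloc_cd68_m1_pct",
    "CD163_M2": "coloc_cd163_m2_pct",
}


def _read_config(path=None) -> configparser.ConfigParser:
    parser = configparser.ConfigParser()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            parser.read_file(fh)
    else:
        text = resources.files(__package__).joinpath("severity.cfg").read_text(encoding="utf-8")
        parser.read_string(text)
    return parser


def preset_config(group: str, path=None, **overrides) -> SimulationConfig:
    """Build the SimulationConfig for one severity group.

    ``overrides`` replace any :class:`SimulationConfig` field (e.g. a larger
    ``region_width`` for higher-precision runs).
    """
    parser = _read_config(path)
    if group not in PRESET_GROUPS:
        raise ValueError(f"unknown preset group: {group!r} (expected one of {PRESET_GROUPS})")
    shared = parser["shared"]
    sec = parser[group]
    jshare = shared.getfloat("juxtacrine_share")
    pf = sec.getfloat("partner_fraction_pct") / 100.0
    partner_fractions = {p: pf for p in _COLOC_KEYS}
    partner_fractions["CD3"] = shared.getfloat("cd3_fraction_pct") / 100.0
    coupling = {}
    for pheno, key in _COLOC_KEYS.items():
        c = sec.getfloat(key) / 100.0
        coupling[pheno] = (jshare * c, (1.0 - jshare) * c)
    cfg = SimulationConfig(
        region_width=shared.getfloat("region_width_um"),
        region_height=shared.getfloat("region_height_um"),
        total_cell_density=shared.getfloat("total_cell_density_per_mm2"),
        mc_fraction=sec.getfloat("mc_fraction_pct") / 100.0,
        cluster_mean_offspring=sec.getfloat("cluster_mean_offspring"),
        cluster_radius_sd=shared.getfloat("cluster_radius_sd_um"),
        partner_fractions=partner_fractions,
        coupling=coupling,
        nuclear_semiaxis_mean=shared.getfloat("nuclear_semiaxis_mean_um"),
        nuclear_semiaxis_sd=shared.getfloat("nuclear_semiaxis_sd_um"),
    )
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise ValueError(f"unknown SimulationConfig field: {k}")
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def default_cohort_design(path=None, **overrides) -> CohortDesign:
    """The full study design: group sizes and presets from the config file."""
    parser = _read_config(path)
    sizes = {g: parser[g].getint("n_samples") for g in PRESET_GROUPS}
    configs = {g: preset_config(g, path=path, **overrides) for g in PRESET_GROUPS}
    return CohortDesign(group_sizes=sizes, configs=configs)
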