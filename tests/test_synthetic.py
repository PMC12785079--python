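"""Synthetic cohort generator: determinism, budgets, coupling recovery."""

import numpy as np
import pandas as pd
import pytest

from mcspatial.errors import CouplingInfeasibleError
from mcspatial.grading import grade
from mcspatial.interactions import interaction_profile
from mcspatial.presets import default_cohort_design, preset_config
from mcspatial.synthetic import (
    CohortDesign,
    SimulationConfig,
    simulate_cohort,
    simulate_morphometry,
    simulate_sample,
)


class TestSimulateSample:
    def test_zero_mc_fraction_gives_no_mast_cells(self, small_config):
        small_config.mc_fraction = 0.0
        small_config.coupling = {}
        s = simulate_sample(small_config, seed=1)
        assert (s.detections["phenotype"] == "MC").sum() == 0

    def test_all_cells_inside_region_and_semiaxes_positive(self, small_config):
        s = simulate_sample(small_config, seed=2)
        xy = s.coords()
        assert (xy[:, 0] >= 0).all() and (xy[:, 0] <= small_config.region_width).all()
        assert (xy[:, 1] >= 0).all() and (xy[:, 1] <= small_config.region_height).all()
        assert (s.detections["nuc_major_um"] > 0).all()

    def test_deterministic_under_fixed_seed(self, small_config):
        a = simulate_sample(small_config, seed=7).detections
        b = simulate_sample(small_config, seed=7).detections
        pd.testing.assert_frame_equal(a, b)

    def test_phenotype_fractions_recovered_over_replicates(self, small_config):
        # over >= 20 replicates each phenotype's empirical fraction should sit
        # within 3 SE of its configured fraction
        counts = {"MC": 0, "CD8": 0, "CD14": 0}
        total = 0
        for i in range(20):
            s = simulate_sample(small_config, seed=100 + i)
            vc = s.phenotype_counts()
            total += s.n_cells
            for p in counts:
                counts[p] += int(vc.get(p, 0))
        expected = {"MC": small_config.mc_fraction, "CD8": 0.01, "CD14": 0.01}
        for p, f in expected.items():
            se = np.sqrt(f * (1 - f) / total)
            # MC counts are cluster-overdispersed; widen by the Thomas factor
            infl = np.sqrt(1 + small_config.cluster_mean_offspring) if p == "MC" else 1.0
            assert abs(counts[p] / total - f) < 3 * se * infl, p

    def test_full_coupling_places_every_mc_in_contact(self):
        cfg = SimulationConfig(
            region_width=2000.0, region_height=2000.0, total_cell_density=3000.0,
            mc_fraction=0.01, cluster_mean_offspring=3.0, cluster_radius_sd=50.0,
            partner_fractions={"CD8": 0.05}, coupling={"CD8": (1.0, 0.0)},
        )
        s = simulate_sample(cfg, seed=3)
        p = interaction_profile(s, "MC", "CD8")
        assert p.n_source >= 100
        assert p.pct_juxtacrine == pytest.approx(100.0)

    def test_coupling_fraction_recovered_monte_carlo(self, small_config):
        # coupling (0.10, 0.18): fraction of MCs with nearest CD8 <= 20 µm
        # should estimate 0.28 within 3 binomial SE
        n_coloc = n_mc = 0
        for i in range(10):
            s = simulate_sample(small_config, seed=500 + i)
            p = interaction_profile(s, "MC", "CD8")
            n_mc += p.n_source
            n_coloc += p.n_juxtacrine + p.n_paracrine
        assert n_mc >= 500
        se = np.sqrt(0.28 * 0.72 / n_mc)
        assert abs(n_coloc / n_mc - 0.28) < 3 * se

    def test_per_band_fractions_recovered(self, small_config):
        nj = np_ = n = 0
        for i in range(10):
            s = simulate_sample(small_config, seed=900 + i)
            p = interaction_profile(s, "MC", "CD8")
            n += p.n_source
            nj += p.n_juxtacrine
            np_ += p.n_paracrine
        for frac, target in ((nj / n, 0.10), (np_ / n, 0.18)):
            se = np.sqrt(target * (1 - target) / n)
            assert abs(frac - target) < 3 * se

    def test_coupling_beyond_partner_budget_rejected(self):
        cfg = SimulationConfig(
            region_width=2000.0, region_height=2000.0, total_cell_density=3000.0,
            mc_fraction=0.05, partner_fractions={"CD8": 0.001},
            coupling={"CD8": (0.5, 0.4)},
        )
        with pytest.raises(CouplingInfeasibleError):
            simulate_sample(cfg, seed=1)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(mc_fraction=0.9, partner_fractions={"CD8": 0.2}).validate()


class TestSimulateCohort:
    def test_default_design_has_study_group_sizes(self):
        design = default_cohort_design(
            region_width=400.0, region_height=400.0, total_cell_density=500.0
        )
        samples = simulate_cohort(design, seed=1)
        assert len(samples) == 63
        groups = pd.Series([s.group for s in samples]).value_counts()
        assert groups.to_dict() == {"SCE": 19, "MiCE": 18, "MoCE": 16, "control": 10}

    def test_singleton_groups(self):
        design = default_cohort_design(
            region_width=400.0, region_height=400.0, total_cell_density=500.0
        )
        design.group_sizes = {g: 1 for g in design.group_sizes}
        assert len(simulate_cohort(design, seed=1)) == 4

    def test_same_seed_reproduces_detection_tables(self):
        design = default_cohort_design(
            region_width=500.0, region_height=500.0, total_cell_density=1000.0
        )
        design.group_sizes = {"control": 2, "severe": 2}
        design.configs = {g: design.configs[g] for g in design.group_sizes}
        a = simulate_cohort(design, seed=11)
        b = simulate_cohort(design, seed=11)
        for sa, sb in zip(a, b):
            assert sa.sample_id == sb.sample_id
            pd.testing.assert_frame_equal(sa.detections, sb.detections)


class TestSimulateMorphometry:
    @pytest.mark.parametrize("g", ["mild", "moderate", "severe"])
    def test_round_trip_with_grader(self, g):
        for seed in range(25):
            rec = simulate_morphometry(g, seed=seed)
            assert grade(rec).grade == g

    def test_severe_ranges(self):
        for seed in range(20):
            rec = simulate_morphometry("severe", seed=seed)
            assert rec.fibrosis is True
            assert rec.lumen_area <= 99
            assert rec.diameter <= 7.9
            assert rec.cd138_count >= 4

    def test_mild_has_at_most_one_plasma_cell(self):
        assert all(
            simulate_morphometry("mild", seed=s).cd138_count <= 1 for s in range(20)
        )

    def test_unknown_grade_rejected(self):
        with pytest.raises(ValueError):
            simulate_morphometry("normal", seed=0)


class TestPresets:
    def test_preset_mc_fractions_follow_severity(self):
        fr = [preset_config(g).mc_fraction for g in ("control", "mild", "moderate", "severe")]
        assert fr == sorted(fr)
        assert fr[0] == pytest.approx(0.00014)
        assert fr[3] == pytest.approx(0.00206)

    def test_preset_coupling_sums_match_targets(self):
        cfg = preset_config("severe")
        pj, pp = cfg.coupling["CD8"]
        assert pj + pp == pytest.approx(0.280)
        assert pp / pj == pytest.approx(2.0)
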