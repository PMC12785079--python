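# Per-group simulation presets for the synthetic endometrial cohort.
#
# mc_fraction_pct            mast cells as % of total segmented cells
# coloc_*_pct                target % of MCs whose nearest partner of that
#                            phenotype lies within 20 um (juxtacrine+paracrine);
#                            split juxtacrine:paracrine = 1:2 by juxtacrine_share
# partner_fraction_pct       each coupled partner phenotype's % of total cells
# cd3_fraction_pct           uncoupled CD3 population % of total cells
# cluster_mean_offspring     mean MCs per accumulation locus (Thomas process)

[shared]
region_width_um = 3200
region_height_um = 3200
total_cell_density_per_mm2 = 3000
cluster_radius_sd_um = 60
nuclear_semiaxis_mean_um = 4.0
nuclear_semiaxis_sd_um = 1.0
juxtacrine_share = 0.3333333333333333
cd3_fraction_pct = 3.0

[control]
n_samples = 10
mc_fraction_pct = 0.014
cluster_mean_offspring = 1
partner_fraction_pct = 0.5
coloc_cd8_pct = 4.6
coloc_cd14_pct = 5.6
coloc_cd68_m1_pct = 5.6
coloc_cd163_m2_pct = 3.4

[mild]
n_samples = 18
mc_fraction_pct = 0.067
cluster_mean_offspring = 3
partner_fraction_pct = 1.0
coloc_cd8_pct = 11.6
coloc_cd14_pct = 18.7
coloc_cd68_m1_pct = 13.5
coloc_cd163_m2_pct = 9.6

[moderate]
n_samples = 16
mc_fraction_pct = 0.113
cluster_mean_offspring = 4
partner_fraction_pct = 1.5
coloc_cd8_pct = 18.5
coloc_cd14_pct = 26.8
coloc_cd68_m1_pct = 17.4
coloc_cd163_m2_pct = 9.1

[severe]
n_samples = 19
mc_fraction_pct = 0.206
cluster_mean_offspring = 5
partner_fraction_pct = 2.0
coloc_cd8_pct = 28.0
coloc_cd14_pct = 28.8
coloc_cd68_m1_pct = 24.6
coloc_cd163_m2_pct = 21.5
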