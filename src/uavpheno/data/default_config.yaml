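# Study-scale run configuration (see uavpheno.config.RunConfig).
# Two complete-block trials, four UAV missions (two sensors x two
# phenological stages), bare-soil samples included in model training.
seed: 1
outdir: runs/demo
trials:
  - {trial_id: CVT1, n_genotypes: 25, n_replicates: 4}
  - {trial_id: CVT2, n_genotypes: 30, n_replicates: 4}
missions:
  - {id: M1, sensor: PS, stage: milk, noise_sd: 0.010, fcover_scale: 1.0}
  - {id: M2, sensor: P4M, stage: milk, noise_sd: 0.008, fcover_scale: 1.0}
  - {id: M3, sensor: PS, stage: dough, noise_sd: 0.020, fcover_scale: 0.45}
  - {id: M4, sensor: P4M, stage: dough, noise_sd: 0.018, fcover_scale: 0.45}
n_soil: 60
soil_noise_sd: 0.01
split_fraction: 0.6666666666666666
cv_folds: 10
heritability_basis: entry_mean
biophysical_replicates: [1, 2]
biophysical_traits: [LAI, fAPAR, fCover, LCC]
ml_methods: [plsr, rfr, krr, gpr]
parametric_families: null   # null = all 14 index families
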