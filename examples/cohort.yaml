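# Synthetic cohort: 24 subjects, 1 seed + 22 targets per hemisphere,
# strong planted coupling between the right-hemisphere seed and ROI 4.
n_subjects: 24
grid_shape: [24, 32, 32]
voxel_size_mm: 2.0
n_rois: 23
seed_roi: 1
coupled_roi: 4
coupling_strength: 0.9
subscale_loadings: [0.7, 0.8, 0.6]
noise_sd: 0.25
rng_seed: 42
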