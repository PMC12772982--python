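# Phantom cohort parameters for `cervhsi simulate` (CohortSpec fields).
n_subjects: 11
image_height: 72
image_width: 72
grid_start_nm: 500
grid_step_nm: 5
grid_end_nm: 995
view_scale: 1.5
n_examiners: 5
boundary_jitter_sd: 5.0
dilation_bias_range: [-3.0, 3.0]
omission_probability: 0.0
landmark_noise_sd: 0.3
noise_sd: 0.004
hemoglobin_multiplier: [1.6, 2.4]
water_multiplier: [1.5, 2.1]
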