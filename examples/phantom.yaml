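# Synthetic head generator parameters (defaults shown; all keys optional).
# Pass to `datspect phantom --config examples/phantom.yaml --out head.nii.gz`
# or load with SyntheticHeadParams.from_yaml().
shape: [256, 256, 128]
spacing: [1.1, 1.1, 1.4]
head_semiaxes_mm: [79.0, 104.0, 80.0]
brain_semiaxes_mm: [66.0, 92.0, 60.0]
skull_gap_mm: 2.0
skull_thickness_mm: 7.0
sulcus_spacing_mm: 36.0
sulcus_width_mm: 1.8
sulcus_depth_frac: 0.30
white_frac: 0.78
striatum_target_cm3: 17.92
background_target_cm3: 1387.41
seed: 0
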