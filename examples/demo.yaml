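# Minimal demo run: 2 subjects x 2 frontal-cortex fields, all-cells mode.
seed: 11
out_dir: runs/demo
region: frontal_cortex
probe: sense
mode: all_cells
n_subjects: 2
fields_per_subject: 2
n_validation_fields: 4
background_percentile: 5
speckle_k: 5.0
image_shape: [192, 192]
n_planes: 4
validation_floors:
  concordance_r: 0.0
  nucleus_count_error: 0.25
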