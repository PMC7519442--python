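# Default two-group destructive-sampling tissue study design:
# eight tissues, seven sampling times, six animals per point per group
# (three per sex; sex-specific organs contribute one sex only).
tissues: [heart, liver, spleen, lung, kidney, uterus, ovary, testes]
sex_specific:
  heart: both
  liver: both
  spleen: both
  lung: both
  kidney: both
  uterus: female_only
  ovary: female_only
  testes: male_only
time_points_min: [10, 30, 90, 180, 360, 480, 720]
animals_per_point_per_group: 6
groups: [crude, salt_processed]
dose_volume_per_bw: 1.2      # mL per 200 g body weight
homogenate_dilution_factor: 3.0   # tissue + two volumes of saline
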