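# Minimal simulation config for `neocohort simulate`.
# Omitted cohort fields fall back to the study-shaped defaults
# (burden median 66, dispersion 2.0, C>T fraction 0.45, age effect 1.5).
seed: 1
proteome:
  n_genes: 40
  min_len: 300
  max_len: 800
cohort:
  n_samples: 30
  burden_median: 25.0
  hla_frequencies:
    HLA-A11:01: 0.6
    HLA-A24:02: 0.4
    HLA-B40:01: 0.6
    HLA-B46:01: 0.4
    HLA-C07:02: 1.0
binding:
  motif_strength: 0.9
  noise_sd: 0.05
  n_tools: 3
common_fraction: 0.05
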