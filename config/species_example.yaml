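# Per-species length-weight parameters (W = a * L^b, W in g, L = fork
# length in mm) and the biomass cutoff separating juveniles from mature
# adults. The values below are placeholders with realistic magnitudes for
# medium-bodied demersal fishes — replace them with published estimates
# for your study species before any real analysis.
dhufish_like:
  a_male: 2.0e-5
  b_male: 2.95
  a_female: 1.8e-5
  b_female: 2.98
  cutoff_g: 900
snapper_like:
  a_male: 1.5e-5
  b_male: 3.05
  a_female: 1.5e-5     # monomorphic: male = female
  b_female: 3.05
  cutoff_g: 600
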