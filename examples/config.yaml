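# Example configuration for the meatspec CLI.
#
# `generator` fields mirror meatspec.generate.GeneratorConfig;
# `experiment` controls the run command.

generator:
  n_days: 5
  carcasses_per_day: 5
  # cut_types default to the six standard cuts
  wavelength_start: 400.0
  wavelength_stop: 1000.0
  wavelength_step: 0.6
  band_centers: [430.0, 550.0, 760.0, 980.0]
  band_widths: [25.0, 30.0, 35.0, 40.0]
  scatter_multiplicative_sd: 0.05
  scatter_additive_sd: 0.03
  baseline_tilt_sd: 0.0003
  noise_sd: 0.005
  replicates_per_sample: 5
  seed: 1

experiment:
  trim: [400, 1000]
  chains: [original, msc, snv, sg, sg_1der, sg_2der, sg_detrend_msc, sg_detrend_snv]
  properties: [pH, L_star, a_star, b_star, cooking_loss, shear_force]
  split: gradient      # or: carcass
  seed: 1
  max_components: 15
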