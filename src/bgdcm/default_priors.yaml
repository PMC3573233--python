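# Default model configuration: synaptic constants, prior connection gains,
# conduction delays, noise spectra and prior standard deviations.
# These are reconstructed defaults chosen to place the loop's dominant
# resonance in the beta band (13-35 Hz) at prior mean; they are documented
# as package defaults, not authoritative constants, and any value can be
# overridden by a user-supplied YAML of the same shape.

subpopulation:
  He: 4.0        # mV, max excitatory postsynaptic amplitude
  Hi: 32.0       # mV, max inhibitory postsynaptic amplitude
  kappa_e: 250.0 # 1/s, excitatory rate constant (kernel peak at 4 ms)
  kappa_i: 100.0 # 1/s, inhibitory rate constant (kernel peak at 10 ms)
  rho1: 2.0      # 1/mV, sigmoid slope
  rho2: 1.0      # mV, sigmoid offset

delays:
  extrinsic_ms: 2.0
  intrinsic_ms: 1.0

# Intrinsic (within-cortex) gains; three-population layered convention.
intrinsic_gains:
  input_to_pyramidal: 32.0
  input_to_interneuron: 32.0
  pyramidal_to_input: 16.0
  pyramidal_to_interneuron: 16.0
  interneuron_to_pyramidal: 64.0

# Extrinsic prior-mean gains (condition ON).  The reciprocal STN-GPe pair
# is the loop's beta resonator; its product sets proximity to instability.
extrinsic_gains:
  ctx_str: 24.0
  ctx_stn: 200.0
  str_gpe: 24.0
  str_gpi: 24.0
  gpe_stn: 110.0
  stn_gpe: 70.0
  stn_gpi: 120.0
  gpi_tha: 120.0
  tha_ctx: 200.0

# Prior gains of the extra connections in the variant architectures.
# weaker priors for the less well-studied pallidofugal projections
variant_gains:
  gpe_gpi: 8.0
  gpe_str: 8.0

# Innovation (neuronal) and channel (measurement) noise spectra:
# g(f) = white + pink / f^exponent, per innovation site / channel.
noise:
  innovation_white: 1.0e-2
  innovation_pink: 1.0e-2
  channel_white: 1.0e-6
  channel_pink: 1.0e-6
  exponent: 1.0
  # fixed relative innovation amplitude per site (order of innovation_sites:
  # cortical input layer, striatum, STN); the cortical weight is kept small
  # so the EEG channel is not swamped by local broadband input
  site_weights: [0.25, 1.0, 1.0]

# Observation gains (channel = gain * membrane potential of mapped
# population); one per channel, log-parameterized.
observation_gain: 1.0

# Prior standard deviations of the log-deviation parameters.
prior_sd:
  log_gain: 0.25
  log_mod: 0.25
  log_he: 0.1
  log_kappa: 0.1
  log_delay: 0.1
  log_obs: 0.5
  log_innov_white: 0.5
  log_innov_pink: 0.5
  log_chan_white: 0.5
  log_chan_pink: 0.5

# Frequency window of interest (Hz).
band: [13.0, 35.0]
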