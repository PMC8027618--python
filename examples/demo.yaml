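# Demo configuration: the full synthetic study with default conditions.
# Run:  crisprcost run --config examples/demo.yaml --out demo-out
seed: 0
log_level: INFO
stages: [dynamics, spacers, estimators, expression]
evolution_experiment: true     # enable the escape-phage extension for the trajectory

model:
  r: 1.0            # maximal growth rate (per h)
  K: 1.0e+9         # carrying capacity (CFU/mL)
  c_sm: 0.001       # constitutive cost of surface mutation
  a: 1.0e-9         # adsorption rate (mL/h)
  b: 50             # burst size
  d: 0.1            # free-phage decay (per h)
  tau_tox: 0.05     # induced toxicity: P(infection kills a CRISPR-immune cell)
  p: 0.01           # spacer acquisition probability per surviving infection
  q_self: 0.0       # fraction of acquisitions that self-target

protocol:
  dilution: 0.01
  phage_added: 1.0e+7
  culture_volume: 6.0
  n_days: 30
  day_length: 24.0
  S0: 1.0e+6
  V0: 1.0e+7

spacer_sim:
  n_events: 10000
  read_depth: 1000000
  frac_self: 1.02e-4
  pam_canonical_ratio: 2.0
  selection_against_self_canonical: 0.05
  priming_center: 27847
  priming_spread: 2000.0

expr_sim:
  n_host_genes: 200
  n_phage_genes: 51
  n_replicates: 5
  phage_attenuation: 5.0
  library_size: 1.0e+6
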