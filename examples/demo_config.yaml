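# Demo run: all four stages on small cohorts.
seed: 1
stages: [transport, morphology, potential, flux]

transport:
  presets: [wt_7div, a53t_7div]
  n_seeds: 2
  compare:
    - [wt_7div, a53t_7div]

morphology:
  presets: [wt_len, a53t_len]
  n_seeds: 2
  compare:
    - [wt_len, a53t_len]

potential:
  groups:
    wt: 100.0
    a53t: 70.0
  control: wt
  n_cells: 30
  intensity_sd: 5.0

flux:
  presets: [wt_flux, a53t_flux]
  n_wells: 6
  compare:
    - [wt_flux, a53t_flux]
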