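seed: 7
n_neurons: 60
neuron: {f0: 100.0, noise_sd: 2.0, spont_amplitude: 20.0, resp_amplitude_max: 0.0}
protocol:
  frame_rate: 2.0
  segments:
    - {label: baseline, duration_s: 300.0, spont_rate_per_min: 0.16}
    - {label: drug, duration_s: 300.0, compound: glutamate, concentration_M: 3.0e-6, spont_rate_per_min: 0.38}
    - {label: kcl, duration_s: 60.0, compound: KCl, concentration_M: 25.0e-3}
dose_response: {n_neurons_per_conc: 50, noise_sd: 0.05}
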