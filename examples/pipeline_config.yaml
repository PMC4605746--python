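# Full pipeline configuration: two 25 Hz neurons sharing a 40 Hz
# oscillatory drive with identical preferred phases, 50 trials of 2 s.
# Run with:  oscsync run --config examples/pipeline_config.yaml
seed: 2024
scenario: pair
mean_rate: 25.0
trial_length: 2.0
n_trials: 50
delta_phi_pref: 0.0
mod_amplitude: 0.7
osc_freq: 40.0
stim_depth: 0.4
refractory_tau: 0.004
bin_width: 0.001
sync_delta: 0.005
penalty: 1.0
n_bootstrap: 400
out_dir: oscsync_run
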