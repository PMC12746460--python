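# Scaled-down 7-site run: synthetic chromophore-specific densities,
# 200 disorder realizations, 2 ps rate-integral horizon, 500 modes.
# Production values (30 ps horizon, 4000 modes, 10000 realizations) are the
# config defaults; they are overridden here to keep the run at ~30 s.
temperature_K: 300.0
preset: fmo7
n_modes: 500
t_max_rate_fs: 2000.0
n_realizations: 200
seed: 1
store_stride: 10
output: fmo_quick_result.h5
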