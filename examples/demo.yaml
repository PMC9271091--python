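# Minimal end-to-end demonstration: two movie groups (with and without
# condensation), one kymograph, and two dual-trap traces.
seed: 1
out_dir: runs/demo

movies:
  groups:
    - name: demo
      n_tethers: 4
      condensate:
        forced_nucleation_time_s: 15.0
        collapse_time_s: 8.0
      tether:
        envelope_sigma_nm: 300.0
      sim:
        n_frames: 120
        image_shape: [48, 160]
        noise: {background_mean: 10, background_sd: 4, photon_gain: 1.0}
    - name: bare
      n_tethers: 2
      tether:
        envelope_sigma_nm: 300.0
      sim:
        n_frames: 120
        image_shape: [48, 160]
        noise: {background_mean: 10, background_sd: 4, photon_gain: 1.0}

kymograph:
  n_foci: 3
  D_list: [0.01, 0.01, 0.01]
  length_um: 12.0
  sim:
    n_frames: 300
    noise: {background_mean: 10, background_sd: 3, photon_gain: 1.0}

traces:
  - name: passive7
    mode: passive
    condensate: {stall_force_pN: 7.0}
    params: {initial_force_pN: 0.5}
    sim: {n_frames: 600}
  - name: clamp05
    mode: clamp
    condensate: {stall_force_pN: 7.0}
    params: {clamp_force_pN: 0.5}
    sim: {n_frames: 300}
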