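# A compact end-to-end study: coarser grid and the three regression-style
# algorithms, two GCMs, two scenarios. Runs in well under a minute.
seed: 7
output_dir: quickstart_run
synthetic:
  resolution: 0.1
  n_presence: 400
  n_transects: 255
  seed: 0
n_pseudo_absences: 2000
algorithms: [GLM, GAM, MAXENT]
gcm_ids: [GCM-A, GCM-B]
rcps: [2.6, 8.5]
years: [2070]
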