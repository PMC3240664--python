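outdir: demo_out
seed: 1
windows_bp: [10000, 4000]
segment_bp: 500
n_samples: 2000
simulation:
  seed: 1
  n_loci: 80
  n_silent_loci: 40
  active_proteins:
    - {name: act1, detection_prob: 0.95}
    - {name: act2, detection_prob: 0.95}
    - {name: act3, detection_prob: 0.9}
  silent_pcg_proteins:
    - {name: pcg1}
    - {name: pcg2}
  silent_insulator_proteins:
    - {name: ins1}
    - {name: ins2}
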