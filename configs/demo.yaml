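# Small demonstration pipeline: a reduced cohort with full gaze streams.
mode: simulate
seed: 7
out_dir: ymaze_demo
cohort:
  size_scale: 0.15
  stream_detail: full
stages: [simulate, metrics, gaze, stats, predict]
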