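# Full pipeline demo on the default simulated experiment.
#   starr run --config demo.yaml
outdir: scratch/pipeline
simulate:
  seed: 1
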