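# Example end-to-end run configuration (see isletorigin.pipeline.RunConfig
# for every available field and its default).
seed: 7
outdir: demo_run
cv_reps: 100
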