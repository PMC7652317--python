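trial: mitra_fr
output_dir: results
analysis:
  # published equivalent-HR bounds used for the survival-CI factor
  os_hazard_variation: 0.20
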