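# Default experiment configuration.
# Constants below mirror the study design: 20 fruits per (drop height, day)
# group; drop heights 0.5 / 1.0 / 1.5 m plus an undamaged control; imaging
# days 1, 3, 5; 256 spectral bands over 900-1700 nm; 3/5 calibration split
# for regression, 3/4 training split for classification; 50 CARS sampling
# runs; ripening-index severity cut points at 7.0 and 5.0.

seed: 0
output_dir: runs/default

simulate:
  n_fruits: 20            # fruits per (height, day) group
  heights: [0.0, 0.5, 1.0, 1.5]   # metres; 0.0 is the undamaged control
  days: [1, 3, 5]

preprocessing: snv        # snv | sg | msc | none
sg:
  window: 11
  polyorder: 2

split:
  calibration_ratio: 0.6  # 3/5 -> 12 calibration / 8 validation per 20-fruit group
  train_ratio: 0.75       # 3/4 training split for the damage classifier

cars:
  enabled: true
  n_runs: 50              # Monte-Carlo sampling iterations
  mc_sample_ratio: 0.8
  pls_components: 5

pls:
  max_components: 10      # leave-one-out CV chooses the final count

rpi_thresholds:
  slight_min: 7.0         # RPI above this -> slightly damaged
  serious_max: 5.0        # RPI below this -> seriously damaged

mode: per_group           # per_group (attribute x height x day) | pooled
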