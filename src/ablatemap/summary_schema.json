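{
 "type": "object",
 "required": [
  "n_cells", "n_responders", "near_ttp_mean", "near_ttp_sd", "n_near",
  "ablation_radius", "far_slope", "wave_speed", "train_counts",
  "peak_train", "n_double_labeled"
 ],
 "properties": {
  "n_cells": {"type": "integer"},
  "n_responders": {"type": "integer"},
  "near_ttp_mean": {"type": ["number", "null"]},
  "near_ttp_sd": {"type": ["number", "null"]},
  "n_near": {"type": "integer"},
  "ablation_radius": {"type": ["number", "null"]},
  "ablation_radius_ci": {"type": ["array", "null"]},
  "far_slope": {"type": ["number", "null"]},
  "far_intercept": {"type": ["number", "null"]},
  "wave_speed": {"type": ["number", "null"]},
  "train_counts": {"type": "array"},
  "peak_train": {"type": ["integer", "null"]},
  "n_double_labeled": {"type": "integer"},
  "provenance": {
   "type": "object",
   "properties": {
    "version": {"type": "string"},
    "seed": {"type": ["integer", "null"]},
    "config_hash": {"type": "string"}
   }
  }
 }
}
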