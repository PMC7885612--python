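{
  "features": [
    "capillary_refill_rate",
    "diastolic_blood_pressure",
    "fraction_inspired_oxygen",
    "gcs_eye_opening",
    "gcs_motor_response",
    "gcs_total",
    "gcs_verbal_response",
    "glucose",
    "heart_rate",
    "height",
    "mean_blood_pressure",
    "oxygen_saturation",
    "respiratory_rate",
    "systolic_blood_pressure",
    "temperature",
    "weight",
    "ph"
  ]
}
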