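{
  "capillary_refill_rate": 0.0,
  "diastolic_blood_pressure": 59.0,
  "fraction_inspired_oxygen": 0.21,
  "gcs_eye_opening": 4.0,
  "gcs_motor_response": 6.0,
  "gcs_total": 15.0,
  "gcs_verbal_response": 5.0,
  "glucose": 128.0,
  "heart_rate": 86.0,
  "height": 170.0,
  "mean_blood_pressure": 77.0,
  "oxygen_saturation": 98.0,
  "respiratory_rate": 19.0,
  "systolic_blood_pressure": 118.0,
  "temperature": 36.6,
  "weight": 81.0,
  "ph": 7.4
}
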