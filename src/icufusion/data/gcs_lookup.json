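{
  "spontaneously": 4,
  "to speech": 3,
  "to pain": 2,
  "none": 1,
  "obeys commands": 6,
  "localizes pain": 5,
  "flex-withdraws": 4,
  "abnormal flexion": 3,
  "abnormal extension": 2,
  "no response": 1,
  "oriented": 5,
  "confused": 4,
  "inappropriate words": 3,
  "incomprehensible sounds": 2,
  "no response-ett": 1
}
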