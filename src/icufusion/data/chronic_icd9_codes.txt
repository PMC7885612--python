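# Chronic-condition ICD-9 codes (undotted), one per line.
# A representative list of common chronic diagnoses; extend or replace via config.
4019
40390
4280
42731
41401
412
2724
25000
25002
496
49390
49121
5859
5856
5712
5715
57140
3310
332
340
2859
28521
530081
V4581
V5861
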