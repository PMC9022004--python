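patient,tailor_1mm,icru_1mm,homogeneity_1mm,tailor_3mm,icru_3mm,homogeneity_3mm
1,78.53,73.68,72.80,96.07,94.28,94.85
2,89.78,80.91,75.87,98.69,92.91,96.58
3,84.57,78.19,73.70,98.33,94.35,97.39
4,90.65,83.23,83.26,99.45,97.21,97.68
5,80.91,73.99,73.30,96.82,92.83,95.18
6,90.87,83.93,84.49,98.42,95.57,97.95
7,89.02,81.60,76.11,97.93,95.44,96.28
8,85.23,78.76,78.17,96.75,93.77,95.82
9,88.86,82.76,83.87,97.13,93.97,96.65
10,89.48,81.02,74.00,98.46,92.35,96.65
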