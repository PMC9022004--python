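patient,tailor,icru,homogeneity
1,-0.33,-6.13,3.41
2,-1.28,-6.26,-1.47
3,-1.33,-8.38,1.45
4,0.15,-9.94,4.88
5,0.95,-9.27,-1.39
6,3.42,-5.41,5.74
7,-0.65,-7.23,2.18
8,-0.45,-11.37,1.23
9,0.16,-11.97,-2.24
10,-2.02,-11.73,2.73
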