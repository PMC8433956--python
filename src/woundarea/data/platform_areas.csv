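label,ref_cm2,test_cm2
1a,3.92,2.70
1b,8.56,6.50
1c,7.52,6.69
1d,4.98,2.52
1e,3.50,2.06
1f,7.07,5.95
1g,6.81,2.91
1h,1.74,0.83
1i,4.58,3.20
1j,2.27,1.16
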