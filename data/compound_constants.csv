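compound,pki,pki_sem,kon,koff,pkb,pa2
37,7.33,0.06,1.60e6,0.075,7.45,
39,7.92,0.06,5.95e6,0.046,,7.95
40,6.79,0.07,0.23e6,0.057,7.05,
47,7.14,0.04,1.49e6,0.049,6.99,
48,7.01,0.05,1.01e6,0.054,7.09,
59,7.04,0.08,0.65e6,0.050,6.95,
60,7.23,0.06,0.35e6,0.102,6.89,
74,7.53,0.06,3.83e6,0.092,7.32,
75,7.56,0.04,2.41e6,0.057,7.39,
76,7.36,0.07,1.12e6,0.081,7.30,
77,6.90,0.03,1.51e6,0.066,6.55,
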