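{
 "w_A0": 0.0,
 "w_A1": 0.917,
 "w_A2": -0.873,
 "w_T0": 0.0,
 "w_T1": 0.788,
 "w_T2": -0.246,
 "w_T3": 0.002,
 "w_T4": 3.066,
 "w_T5": -3.650,
 "w_N0": 0.0,
 "w_N1": 1.627,
 "w_N2": -1.253,
 "w_N3": 0.018,
 "w_N4": 2.342,
 "w_N5": -4.015,
 "w_C0": 0.0,
 "w_C1": 0.159,
 "w_C2": 0.202,
 "w_C3": 0.010,
 "w_C4": 0.019,
 "w_C5": -0.176,
 "y0": 6.35e-6
}
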