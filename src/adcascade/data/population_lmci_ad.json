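{
 "w_A0": 0.0,
 "w_A1": 0.745,
 "w_A2": -0.749,
 "w_T0": 0.0,
 "w_T1": 0.689,
 "w_T2": -0.679,
 "w_T3": 0.0,
 "w_T4": 0.185,
 "w_T5": -0.101,
 "w_N0": 0.0,
 "w_N1": 0.899,
 "w_N2": -0.927,
 "w_N3": 0.554,
 "w_N4": 1.792,
 "w_N5": -2.127,
 "w_C0": 0.0,
 "w_C1": 0.134,
 "w_C2": -0.067,
 "w_C3": 0.004,
 "w_C4": 0.007,
 "w_C5": -0.008,
 "y0": 1.41e-4
}
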