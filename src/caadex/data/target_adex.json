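{
 "C_m_s": 105.03972376035635,
 "g_L_s": 19.5067,
 "E_L_s": -66.004,
 "Delta_T": 2.0,
 "V_th_s": -45.85874730914799,
 "V_th": -30.0,
 "V_reset": -58,
 "t_ref": 2.5,
 "a": 1.0290316381516087,
 "b": 145.57128685180274,
 "tau_w": 60,
 "g_w": 1.0
}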