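{
 "values": {
  "C_m_s": 105.03972376035635,
  "g_L_s": 12.0,
  "E_L_s": -67.63083635338327,
  "g_C": 30.866697487050537,
  "Delta_T": 2.0,
  "V_th_s": -45.85874730914799,
  "V_th": -30.0,
  "V_reset": -58,
  "t_ref": 2.5,
  "a": 1.0290316381516087,
  "b": 145.57128685180274,
  "tau_w": 60,
  "g_w": 1.0,
  "w_BAP": 5919.816672696664,
  "d_BAP": 4.176939309296376,
  "C_m_d": 349.3038682296567,
  "g_L_d": 9.919022289102836,
  "E_L_d": -63.403359116669854,
  "g_Ca": 19.01112192395099,
  "E_Ca": 50.0,
  "m_slope": -0.4,
  "m_half": -26.131171478681267,
  "tau_m_Ca": 4.715643593541348,
  "h_slope": 0.25,
  "h_half": -35.0,
  "tau_h_Ca": 80.0,
  "g_K": 22.704555574884093,
  "E_K": -85.0,
  "tau_m_KCa": 11.020667593259173,
  "Ca_th": 0.00045108294398067564,
  "const_KCa": 4.0,
  "phi_Ca": 1.444379277246823e-07,
  "Ca_0": 0.0001,
  "tau_Ca": 46.415349793380145
 },
 "bounds": {
  "C_m_s": [
   50.0,
   600.0
  ],
  "g_L_s": [
   2.0,
   60.0
  ],
  "E_L_s": [
   -90.0,
   -55.0
  ],
  "g_C": [
   0.0,
   60.0
  ],
  "Delta_T": [
   0.5,
   6.0
  ],
  "V_th_s": [
   -60.0,
   -40.0
  ],
  "V_th": [
   -45.0,
   10.0
  ],
  "V_reset": [
   -90.0,
   -45.0
  ],
  "t_ref": [
   0.0,
   6.0
  ],
  "a": [
   0.0,
   40.0
  ],
  "b": [
   0.0,
   300.0
  ],
  "tau_w": [
   10.0,
   600.0
  ],
  "g_w": [
   0.5,
   2.0
  ],
  "w_BAP": [
   0.0,
   12000.0
  ],
  "d_BAP": [
   0.0,
   5.0
  ],
  "C_m_d": [
   20.0,
   600.0
  ],
  "g_L_d": [
   1.0,
   40.0
  ],
  "E_L_d": [
   -90.0,
   -55.0
  ],
  "g_Ca": [
   0.0,
   40.0
  ],
  "E_Ca": [
   20.0,
   140.0
  ],
  "m_slope": [
   -2.0,
   -0.05
  ],
  "m_half": [
   -45.0,
   -5.0
  ],
  "tau_m_Ca": [
   0.5,
   40.0
  ],
  "h_slope": [
   0.05,
   2.0
  ],
  "h_half": [
   -60.0,
   -10.0
  ],
  "tau_h_Ca": [
   5.0,
   500.0
  ],
  "g_K": [
   0.0,
   60.0
  ],
  "E_K": [
   -100.0,
   -70.0
  ],
  "tau_m_KCa": [
   0.5,
   60.0
  ],
  "Ca_th": [
   1e-05,
   0.01
  ],
  "const_KCa": [
   1.0,
   8.0
  ],
  "phi_Ca": [
   1e-09,
   1e-05
  ],
  "Ca_0": [
   0.0,
   0.001
  ],
  "tau_Ca": [
   10.0,
   500.0
  ]
 }
}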