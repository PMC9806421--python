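{
 "comment": "Default calibrated gating model. Rates in 1/s, voltages in mV. rate(V) = min(base*exp((V-v_half)/efold_mV), cap); efold_mV null = voltage-independent. Calibrated against the printed control values: 100 ms conditioning-pulse availability midpoint near -58 mV, 5 s conditioning midpoint near -59 mV, about half of the current still available after 5 s at +10 mV plus 100 ms recovery at -120 mV, millisecond repriming and sub-second slow recovery at -120 mV. The direct R->SI route (vanishing below about -110 mV) gives slow inactivation a small resting-state floor so that the slow-inactivated fraction persists at hyperpolarized holding potentials where fast inactivation is absent.",
 "rates": {
  "R->O": {
   "base": 800.0,
   "efold_mV": 22.0,
   "v_half": -25.0
  },
  "O->R": {
   "base": 3000.0,
   "efold_mV": -40.0,
   "v_half": -25.0
  },
  "O->FI": {
   "base": 5000.0,
   "efold_mV": null
  },
  "FI->R": {
   "base": 76.0,
   "efold_mV": -26.0,
   "v_half": -58.3
  },
  "FI->SI": {
   "base": 0.16,
   "efold_mV": null
  },
  "SI->FI": {
   "base": 0.1,
   "efold_mV": -22.0,
   "v_half": -60.0
  },
  "R->SI": {
   "base": 0.006,
   "efold_mV": 6.0,
   "v_half": -107.0,
   "cap": 0.006
  }
 },
 "k_assoc": {
  "R": 1.0,
  "O": 1.0,
  "FI": 10.0,
  "SI": 2.0
 },
 "k_off": 1.0
}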