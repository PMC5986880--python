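{
  "_comment": "Default constants of the conductance-based neural-mass node model (version 1). Gains g_* and reversal potentials V_* of the voltage-gated Ca/K/Na channels and the leak; sigmoid thresholds T_*/delta_* of the channel activation curves; firing-rate sigmoid thresholds V_T/Z_T and slopes delta_V/delta_Z; local synaptic gains a_ee (excitatory->excitatory), a_ei, a_ie, a_ne, a_ni; inhibitory rate b, K-channel relaxation rate phi, NMDA/AMPA receptor ratio r_nmda, and the non-specific input I. Any re-tuning of the node model is a new version of this file.",
  "version": 1,
  "g_ca": 1.0,
  "g_k": 2.0,
  "g_l": 0.5,
  "g_na": 6.7,
  "v_ca": 1.0,
  "v_k": -0.7,
  "v_l": -0.5,
  "v_na": 0.53,
  "t_ca": -0.01,
  "delta_ca": 0.15,
  "t_k": 0.0,
  "delta_k": 0.3,
  "t_na": 0.3,
  "delta_na": 0.15,
  "v_t": 0.0,
  "z_t": 0.0,
  "delta_v": 0.65,
  "delta_z": 0.65,
  "q_v_max": 1.0,
  "q_z_max": 1.0,
  "a_ee": 0.3,
  "a_ei": 2.0,
  "a_ie": 2.0,
  "a_ne": 1.0,
  "a_ni": 0.4,
  "b": 0.1,
  "phi": 0.7,
  "r_nmda": 0.25,
  "i_ns": 0.3
}
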