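base:
  ryr:
    k_sens: 1.0
    k_refr: 1.0
    lambda0: 0.35
    K_half: 10.0
    hill_h: 2.0
    tau_refill: 90.0
    gamma_rec: 10.0
    J_rel_max: 0.18
    tau_refr_R: 65.0
    R_reset: 0.0
    tau_open: 9.0
    c_jsr_ref: 1000.0
    het_refr: 0.2
  ca:
    n_cru: 50
    dx: 2.0
    v_ss: 0.001
    v_jsr: 0.01
    v_nsr: 0.05
    beta_sr: 15.0
    b_tot: 120.0
    b_kd: 0.7
    d_ca: 0.3
    tau_ss: 0.15
    v_up: 0.3
    k_up: 0.3
    g_leak: 2.0e-05
    j_bg: 0.0036
    cal_ss_frac: 1.0
    c_rest: 0.1
  mem:
    g_na: 12.0
    g_cal: 0.13
    e_cal: 60.0
    k_fca: 50.0
    g_kr: 0.012
    g_ks: 0.006
    g_to: 0.025
    g_k1: 0.35
    g_nak: 0.4
    g_ncx: 2400.0
    ncx_sub_frac: 0.002
    e_na: 70.0
    e_k: -88.0
    na_i: 10.0
    na_o: 140.0
    ca_o: 1800.0
    km_na: 87.5
    km_ca: 1380.0
    eta: 0.35
    k_sat: 0.27
    cm: 1.0
    current_to_flux: 0.0333
    stim_amp: -40.0
    stim_dur: 1.0
  sim:
    dt: 0.01
    cru_substep: 5
    rec_dt: 1.0
    sarcolemmal_on: true
    max_events: 400000
  iso: false
  species: rabbit
  calibrated: false
cpvt:
  k_sens: 2.25
  k_refr: 0.65
note: 'Frozen calibration: the base block reproduces the control steady-state anchors
  (late-spark rate, SR load, current budget at 50% repolarization); the cpvt block
  holds the fitted RyR2 hyperactivity knobs.'
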