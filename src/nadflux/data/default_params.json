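{
  "comment": "Calibrated defaults: the flux pipeline on noiseless control cohorts reproduces the reported synthesis/consumption rates, the deamidase steady-state NAD+ fraction and the post-injury NMN transient. Produced by analysis/00_calibrate_defaults.py.",
  "parameters": {
    "vmax_nampt": 1.5556505543,
    "km_nampt_nam": 0.1,
    "ki_nampt_nad": 0.8635033691,
    "hill_nampt": 11.9995545803,
    "k_nmnat": 0.6814287893,
    "k_nmnat_namn": 0.01,
    "k_nadsyn": 0.0002758205,
    "k_nrk": 0.0,
    "k_deamidase": 0.0,
    "k_synthetase": 0.0,
    "k_nmn_leak": 0.3843313074,
    "k_cons_basal": 0.1453937357,
    "k_cons_sarm1": 0.3930367546,
    "t_half_nmnat2": 0.35,
    "nmnat_decay_delay_h": 1.6,
    "k_adenylate_decay": 0.7860393351,
    "k_exchange": 0.15,
    "nam_medium": 30.0,
    "d4nam_medium": 300.0,
    "nr_medium": 0.0,
    "nad_init": 1.0,
    "nmn_init": 0.213366001,
    "namn_init": 0.0,
    "naad_init": 0.0,
    "atp_init": 5.0,
    "adp_init": 1.0,
    "amp_init": 0.3,
    "km_nrk": 300.0
  },
  "scenario_constants": {
    "nampt_oe_fold": 5.0,
    "k_nrk": 0.005,
    "k_deamidase": 299.3218637781,
    "k_synthetase": 2.0,
    "nr_dose_uM": {
      "NRK1_NR": 100.0,
      "NMN_DD_SN_NR": 5000.0
    },
    "sarm1_activation": {
      "FK866": 0.0,
      "NAMPT_OE": 0.0,
      "NRK1_NR": 0.0
    },
    "equilibrate_h": 96.0
  }
}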