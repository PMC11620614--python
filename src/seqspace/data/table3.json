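{
  "constants": {
    "A_t": 7.5,
    "nonsynonymous_fraction": 0.69
  },
  "proteins": {
    "beta-lactamase": {
      "length": 263,
      "alpha": 0.104,
      "beta": 0.019,
      "alpha_raw_all_mutations": 0.07176,
      "beta_raw_all_mutations": 0.009048,
      "raw_coefficients_back_derived": true,
      "schedule": [1.0, 0.61, 0.61, 0.55, 0.55, 0.39],
      "printed_p_th": ".00051",
      "printed_n_max": "10-17",
      "printed_si": "93.6-96.2%",
      "source": "Bershtein 2006"
    },
    "GFP": {
      "length": 236,
      "alpha": -0.062,
      "beta": 0.058,
      "fit_exclude_n": [1],
      "printed_p_th": ".00056",
      "printed_n_max": "12",
      "printed_si": "95.0%",
      "source": "Sarkisyan 2016"
    },
    "HisA": {
      "length": 245,
      "alpha": 0.165,
      "beta": 0.065,
      "printed_p_th": ".00054",
      "printed_n_max": "10",
      "printed_si": "95.9%",
      "source": "Lundin 2018"
    }
  }
}
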