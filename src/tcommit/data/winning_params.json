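{
  "description": "Mean and SD of the fitted TCF-1/GATA-3/BCL11B + Notch parameters for the four winning combinatorial configurations, plus the reported effective half-lives in hours. Notch-coupled weights are stored as products with the maximal signal (eta1N = eta_1*N etc.). kappa entries are ordered as in the compiled rate law (Notch-containing minterm first).",
  "models": {
    "6d": {
      "gate": "TCF-1 AND (Notch OR GATA-3)",
      "n_T": 2,
      "n_G": 2,
      "mean": {
        "eta1N": 1.7e0, "eta2": 2.2e-4, "eta3": 3.3e-4, "eta4": 4.7e-5,
        "f_T": 1.3e4, "gamma_T": 2.4e-4,
        "delta1N": 3.0e-4, "delta2": 3.2e-5, "delta3": 1.8e-3,
        "f_G": 1.2e5, "gamma_G": 5.2e-5,
        "kappa": [1.0e-10, 3.6e-14],
        "f_B": 9.2e3, "gamma_B": 1.9e-4,
        "alpha": 5.2e-1
      },
      "sd": {
        "eta1N": 3.6e-1, "eta2": 3.4e-5, "eta3": 2.3e-4, "eta4": 3.1e-5,
        "f_T": 3.3e3, "gamma_T": 6.8e-6,
        "delta1N": 1.9e-3, "delta2": 1.1e-5, "delta3": 6.3e-4,
        "f_G": 3.6e4, "gamma_G": 2.1e-5,
        "kappa": [3.9e-26, 7.3e-16],
        "f_B": 1.5e3, "gamma_B": 1.9e-5,
        "alpha": 3.7e-1
      },
      "half_life_hours": {"T": [5.6, 1.1], "G": [3.0, 0.44], "B": [9.9, 1.4]}
    },
    "7b": {
      "gate": "GATA-3 AND (Notch OR TCF-1)",
      "n_T": 1,
      "n_G": 2,
      "mean": {
        "eta1N": 2.3e0, "eta2": 1.5e-4, "eta3": 6.4e-4, "eta4": 3.4e-5,
        "f_T": 1.2e4, "gamma_T": 2.1e-4,
        "delta1N": 5.9e-6, "delta2": 5.7e-5, "delta3": 1.1e-3,
        "f_G": 5.9e4, "gamma_G": 1.0e-4,
        "kappa": [1.0e-10, 2.7e-11],
        "f_B": 1.2e4, "gamma_B": 8.7e-5,
        "alpha": 1.6e-1
      },
      "sd": {
        "eta1N": 7.5e-1, "eta2": 4.1e-5, "eta3": 1.2e-4, "eta4": 2.2e-5,
        "f_T": 3.7e3, "gamma_T": 2.0e-5,
        "delta1N": 1.6e-5, "delta2": 5.1e-6, "delta3": 7.2e-5,
        "f_G": 8.7e3, "gamma_G": 7.1e-6,
        "kappa": [1.4e-26, 2.5e-13],
        "f_B": 8.0e2, "gamma_B": 1.2e-7,
        "alpha": 6.2e-2
      },
      "half_life_hours": {"T": [7.2, 2.0], "G": [2.9, 0.59], "B": [17.0, 1.2]}
    },
    "7d": {
      "gate": "GATA-3 AND (Notch OR TCF-1)",
      "n_T": 2,
      "n_G": 2,
      "mean": {
        "eta1N": 5.5e0, "eta2": 2.3e-4, "eta3": 7.4e-4, "eta4": 3.3e-5,
        "f_T": 1.3e4, "gamma_T": 2.5e-4,
        "delta1N": 1.4e-3, "delta2": 1.4e-5, "delta3": 1.2e-3,
        "f_G": 1.8e5, "gamma_G": 3.2e-5,
        "kappa": [1.0e-10, 1.1e-14],
        "f_B": 1.2e4, "gamma_B": 7.5e-5,
        "alpha": 2.1e-1
      },
      "sd": {
        "eta1N": 1.7e0, "eta2": 5.92e-5, "eta3": 1.2e-4, "eta4": 1.7e-5,
        "f_T": 2.6e3, "gamma_T": 6.8e-6,
        "delta1N": 3.4e-3, "delta2": 2.83e-6, "delta3": 5.9e-5,
        "f_G": 1.7e4, "gamma_G": 3.7e-6,
        "kappa": [3.9e-26, 5.47e-16],
        "f_B": 1.8e3, "gamma_B": 9.7e-6,
        "alpha": 9.8e-2
      },
      "half_life_hours": {"T": [5.6, 1.25], "G": [3.0, 0.504], "B": [20.0, 3.9]}
    },
    "8b": {
      "gate": "Notch AND TCF-1 AND GATA-3",
      "n_T": 1,
      "n_G": 2,
      "mean": {
        "eta1N": 2.0e0, "eta2": 3.1e-4, "eta3": 6.2e-4, "eta4": 8.1e-6,
        "f_T": 1.4e4, "gamma_T": 2.2e-4,
        "delta1N": 1.9e0, "delta2": 7.7e-4, "delta3": 8.3e-3,
        "f_G": 7.4e3, "gamma_G": 5.7e-4,
        "kappa": [1.0e-10],
        "f_B": 5.3e4, "gamma_B": 1.7e-4,
        "alpha": 3.9e-1
      },
      "sd": {
        "eta1N": 1.4e0, "eta2": 3.9e-5, "eta3": 1.3e-4, "eta4": 4.5e-6,
        "f_T": 2.1e3, "gamma_T": 8.6e-6,
        "delta1N": 4.1e-1, "delta2": 6.4e-5, "delta3": 1.1e-3,
        "f_G": 0.0, "gamma_G": 4.4e-6,
        "kappa": [1.4e-26],
        "f_B": 5.5e4, "gamma_B": 5.1e-5,
        "alpha": 2.1e-1
      },
      "half_life_hours": {"T": [5.41, 0.605], "G": [3.95, 0.0305], "B": [7.2, 10.0]}
    }
  }
}
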