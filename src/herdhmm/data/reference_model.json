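{
  "comment": "Optimal 3-state behaviour model fitted on the full Sahel cattle GPS survey (560,490 fixes, 30-min interval). States in canonical order: resting, foraging, travelling. Step law: zero-truncated normal with untruncated (mu, sigma) in m per 30 min; angles von Mises in rad. The numeric transition matrix of the field fit was published only graphically and is NOT included; supply a Gamma when simulating or decoding.",
  "n_states": 3,
  "step_family": "truncnorm",
  "state_names": ["resting", "foraging", "travelling"],
  "emissions": [
    {"mu": 13.53, "sigma": 11.99, "zeta": 4.2e-4, "mu_angle": -3.05, "kappa": 0.29},
    {"mu": 180.1, "sigma": 149.2, "zeta": 9.5e-13, "mu_angle": 0.0, "kappa": 0.19},
    {"mu": 685.4, "sigma": 439.8, "zeta": 7.13e-12, "mu_angle": -0.0146, "kappa": 1.95}
  ],
  "pi0": [0.4158, 0.3293, 0.2549],
  "p0_dataset": 1.93771e-4
}
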