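{
 "name": "triton_x100",
 "kind": "debye",
 "eps_static": 7.4,
 "eps_inf": 2.4,
 "tau": 2.12e-10,
 "sigma_static": 0.0,
 "density_g_per_mL": 1.07,
 "provenance": "Single-pole Debye fit for pure Triton X-100 at 25 C. Static permittivity from low-frequency literature values for the pure surfactant; relaxation time set so the curve reproduces the ~4 relative permittivity and ~0.1 S/m loss reported for TX-100 around 1 GHz in the microwave-phantom literature. Editable: replace with measured values if available. Density 1.07 g/mL at 25 C (supplier data)."
}
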