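{
 "name": "nerve",
 "kind": "cole_cole",
 "eps_inf": 4.0,
 "sigma_static": 0.006,
 "poles": [
  [
   26.0,
   7.958e-12,
   0.1
  ],
  [
   500.0,
   1.06103e-07,
   0.15
  ],
  [
   70000.0,
   0.000159155,
   0.3
  ],
  [
   40000000.0,
   0.015915,
   0.0
  ]
 ],
 "provenance": "4-pole Cole-Cole parameters from the Gabriel parametric compilation of tissue dielectric properties (Gabriel, Lau & Gabriel, 1996). poles entries are [delta_eps, tau_seconds, alpha]."
}
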