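{
 "name": "blood",
 "kind": "cole_cole",
 "eps_inf": 4.0,
 "sigma_static": 0.7,
 "poles": [
  [
   56.0,
   8.377e-12,
   0.1
  ],
  [
   5200.0,
   1.32629e-07,
   0.1
  ],
  [
   0.0,
   0.000159155,
   0.2
  ],
  [
   0.0,
   0.015915,
   0.0
  ]
 ],
 "provenance": "4-pole Cole-Cole parameters from the Gabriel parametric compilation of tissue dielectric properties (Gabriel, Lau & Gabriel, 1996). poles entries are [delta_eps, tau_seconds, alpha]."
}
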