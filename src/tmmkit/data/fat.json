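{
 "name": "fat",
 "kind": "cole_cole",
 "eps_inf": 2.5,
 "sigma_static": 0.01,
 "poles": [
  [
   3.0,
   7.958e-12,
   0.2
  ],
  [
   15.0,
   1.5915e-08,
   0.1
  ],
  [
   33000.0,
   0.000159155,
   0.05
  ],
  [
   10000000.0,
   0.015915,
   0.01
  ]
 ],
 "provenance": "4-pole Cole-Cole parameters from the Gabriel parametric compilation of tissue dielectric properties (Gabriel, Lau & Gabriel, 1996). poles entries are [delta_eps, tau_seconds, alpha]."
}
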