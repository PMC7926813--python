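{
 "name": "skin_dry",
 "kind": "cole_cole",
 "eps_inf": 4.0,
 "sigma_static": 0.0002,
 "poles": [
  [
   32.0,
   7.234e-12,
   0.0
  ],
  [
   1100.0,
   3.2481e-08,
   0.2
  ],
  [
   0.0,
   0.000159155,
   0.2
  ],
  [
   0.0,
   0.015915,
   0.2
  ]
 ],
 "provenance": "4-pole Cole-Cole parameters from the Gabriel parametric compilation of tissue dielectric properties (Gabriel, Lau & Gabriel, 1996). poles entries are [delta_eps, tau_seconds, alpha]."
}
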