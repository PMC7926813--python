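{
 "name": "bone_cortical",
 "kind": "cole_cole",
 "eps_inf": 2.5,
 "sigma_static": 0.02,
 "poles": [
  [
   10.0,
   1.3263e-11,
   0.2
  ],
  [
   180.0,
   7.9577e-08,
   0.2
  ],
  [
   5000.0,
   0.000159155,
   0.2
  ],
  [
   100000.0,
   0.015915,
   0.0
  ]
 ],
 "provenance": "4-pole Cole-Cole parameters from the Gabriel parametric compilation of tissue dielectric properties (Gabriel, Lau & Gabriel, 1996). poles entries are [delta_eps, tau_seconds, alpha]."
}
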