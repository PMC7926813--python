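{
 "name": "brain_grey_matter",
 "kind": "cole_cole",
 "eps_inf": 4.0,
 "sigma_static": 0.02,
 "poles": [
  [
   45.0,
   7.958e-12,
   0.1
  ],
  [
   400.0,
   1.5915e-08,
   0.15
  ],
  [
   200000.0,
   0.000106103,
   0.22
  ],
  [
   45000000.0,
   0.005305,
   0.0
  ]
 ],
 "provenance": "4-pole Cole-Cole parameters from the Gabriel parametric compilation of tissue dielectric properties (Gabriel, Lau & Gabriel, 1996). poles entries are [delta_eps, tau_seconds, alpha]."
}
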