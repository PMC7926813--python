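{
 "name": "brain_white_matter",
 "kind": "cole_cole",
 "eps_inf": 4.0,
 "sigma_static": 0.02,
 "poles": [
  [
   32.0,
   7.958e-12,
   0.1
  ],
  [
   100.0,
   7.958e-09,
   0.1
  ],
  [
   40000.0,
   5.3052e-05,
   0.3
  ],
  [
   35000000.0,
   0.007958,
   0.02
  ]
 ],
 "provenance": "4-pole Cole-Cole parameters from the Gabriel parametric compilation of tissue dielectric properties (Gabriel, Lau & Gabriel, 1996). poles entries are [delta_eps, tau_seconds, alpha]."
}
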