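{
 "name": "muscle",
 "kind": "cole_cole",
 "eps_inf": 4.0,
 "sigma_static": 0.2,
 "poles": [
  [
   50.0,
   7.234e-12,
   0.1
  ],
  [
   7000.0,
   3.53678e-07,
   0.1
  ],
  [
   1200000.0,
   0.00031831,
   0.1
  ],
  [
   25000000.0,
   0.002274,
   0.0
  ]
 ],
 "provenance": "4-pole Cole-Cole parameters from the Gabriel parametric compilation of tissue dielectric properties (Gabriel, Lau & Gabriel, 1996). poles entries are [delta_eps, tau_seconds, alpha]."
}
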