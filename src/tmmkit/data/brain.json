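{
 "name": "brain",
 "kind": "blend",
 "components": [
  "brain_white_matter",
  "brain_grey_matter"
 ],
 "weights": [
  0.75,
  0.25
 ],
 "provenance": "Reference brain target: volume-weighted blend of 75% white matter and 25% grey matter Cole-Cole models."
}
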