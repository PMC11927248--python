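# Partition of the six subscales into the responsiveness and respectful
# treatment domains used for the two domain-level percentage scores.
spec_version: "1"
responsiveness:
  - "Communication & supportive care"
  - "Hospital environment"
  - "Social support"
respectful:
  - "Maintained respect & dignity"
  - "Maintained privacy & confidentiality"
  - "Lack of physical & verbal abuse"
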