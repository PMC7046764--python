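{
  "_comment": "Indicator score (1-5) to lognormal uncertainty-factor lookup in the style of the data-quality pedigree matrix used by life-cycle inventory databases. Scores 4 (geographical) and 2 (technological) are interpolated monotonically where the published table leaves them undefined.",
  "reliability": [1.0, 1.05, 1.1, 1.2, 1.5],
  "completeness": [1.0, 1.02, 1.05, 1.1, 1.2],
  "temporal": [1.0, 1.03, 1.1, 1.2, 1.5],
  "geographical": [1.0, 1.01, 1.02, 1.05, 1.1],
  "technological": [1.0, 1.05, 1.2, 1.5, 2.0],
  "sample_size": [1.0, 1.02, 1.05, 1.1, 1.2]
}
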