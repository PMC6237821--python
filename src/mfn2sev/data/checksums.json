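{
  "table1_catalog.tsv": "f33a7836257d746f4ab415b2355ddd18084767b1921840598ae8c852664cd458",
  "table1_clinical.tsv": "54341e4d0c33dc1a07df58c8fe351c2430780712748d380a12aa5af50e0bba0f",
  "table2_chains.tsv": "0d47d9e37d96cdf1fa8ed42850411f1a76a5d3f81f43041e2f0ab6766c5430fe"
}
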