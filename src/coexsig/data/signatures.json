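{
  "signatures": [
    {
      "name": "LUAD-8",
      "description": "Eight-gene LUAD prognostic sum-ratio signature; numerator genes are high-expression/high-survival, denominator genes low-expression/high-survival. Larger ratios predict better survival.",
      "numerator_genes": ["ATP6V0E1", "SVBP", "HSDL1", "UBTD1"],
      "denominator_genes": ["GNPNAT1", "XRCC2", "TFAP2A", "PPP1R13L"],
      "invert": false
    }
  ]
}
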