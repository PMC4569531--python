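{
  "_comment": "SYNTHETIC placeholder coefficients in the standard generic ln-ln form ln(AGB kg) = alpha + beta*ln(DBH cm). These are NOT published values; replace with vetted coefficients before any real carbon accounting.",
  "models": [
    {
      "label": "generic eucalypt (synthetic placeholder)",
      "scope": "eucalypt",
      "alpha": -2.2,
      "beta": 2.49,
      "correction_factor": 1.0,
      "source": "synthetic stand-in; non-authoritative"
    },
    {
      "label": "generic rainforest / non-eucalypt (synthetic placeholder)",
      "scope": "non_eucalypt",
      "alpha": -1.9,
      "beta": 2.37,
      "correction_factor": 1.0,
      "source": "synthetic stand-in; non-authoritative"
    }
  ]
}
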