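{
  "comment": "Default base-editor catalog. Windows are inclusive protospacer positions counted from the PAM-proximal end. Cas12a window per dCas12a-BE reports (Li et al. 2018, Nat Biotechnol); SpCas9 BE windows per BE3/ABE7.10 characterization (Komor et al. 2016; Gaudelli et al. 2017).",
  "nucleases": [
    {
      "name": "Cas12a-CBE",
      "motif": "TTTV",
      "motif_side": "5prime_of_protospacer",
      "spacer_length": 23,
      "window": [8, 14],
      "chemistry": "CBE"
    },
    {
      "name": "SpCas9-ABE",
      "motif": "NGG",
      "motif_side": "3prime_of_protospacer",
      "spacer_length": 20,
      "window": [4, 8],
      "chemistry": "ABE"
    },
    {
      "name": "SpCas9-CBE",
      "motif": "NGG",
      "motif_side": "3prime_of_protospacer",
      "spacer_length": 20,
      "window": [4, 8],
      "chemistry": "CBE"
    }
  ]
}
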