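{
  "pathway_id": "ko00860",
  "components": [
    {
      "name": "Tetrapyrrole backbone (glutamate to protoporphyrin IX)",
      "genes": {
        "hemA": "nuclear", "hemL": "nuclear", "hemB": "nuclear",
        "hemC": "nuclear", "hemD": "nuclear", "hemE": "nuclear",
        "hemF": "nuclear", "hemN": "nuclear", "hemY": "nuclear"
      }
    },
    {
      "name": "Chlorophyll branch (Mg-chelation to chlorophyll a)",
      "genes": {
        "chlH": "nuclear", "chlD": "nuclear", "chlI": "nuclear",
        "chlM": "nuclear", "chlE": "nuclear", "dvr": "nuclear",
        "por": "nuclear", "chlG": "nuclear"
      }
    }
  ],
  "chain_input": "glutamyl-tRNA",
  "chain": [
    {"enzyme": "EC 1.2.1.70", "genes": ["hemA"], "product": "glutamate-1-semialdehyde"},
    {"enzyme": "EC 5.4.3.8", "genes": ["hemL"], "product": "5-aminolevulinate"},
    {"enzyme": "EC 4.2.1.24", "genes": ["hemB"], "product": "porphobilinogen"},
    {"enzyme": "EC 2.5.1.61", "genes": ["hemC"], "product": "hydroxymethylbilane"},
    {"enzyme": "EC 4.2.1.75", "genes": ["hemD"], "product": "uroporphyrinogen III"},
    {"enzyme": "EC 4.1.1.37", "genes": ["hemE"], "product": "coproporphyrinogen III"},
    {"enzyme": "EC 1.3.3.3", "genes": ["hemF", "hemN"], "product": "protoporphyrinogen IX"},
    {"enzyme": "EC 1.3.3.4", "genes": ["hemY"], "product": "protoporphyrin IX"},
    {"enzyme": "EC 6.6.1.1", "genes": ["chlH", "chlD", "chlI"], "product": "Mg-protoporphyrin IX"},
    {"enzyme": "EC 2.1.1.11", "genes": ["chlM"], "product": "Mg-protoporphyrin IX monomethyl ester"},
    {"enzyme": "EC 1.21.98.3", "genes": ["chlE"], "product": "divinyl protochlorophyllide"},
    {"enzyme": "EC 1.3.1.75", "genes": ["dvr"], "product": "protochlorophyllide"},
    {"enzyme": "EC 1.3.1.33", "genes": ["por"], "product": "chlorophyllide a"},
    {"enzyme": "EC 2.5.1.62", "genes": ["chlG"], "product": "chlorophyll a"}
  ],
  "aliases": {
    "HemA": "hemA", "HemL": "hemL", "HemB": "hemB", "HemC": "hemC",
    "HemD": "hemD", "HemE": "hemE", "HemF": "hemF", "HemN": "hemN",
    "HemY": "hemY", "DVR": "dvr", "POR": "por"
  }
}
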