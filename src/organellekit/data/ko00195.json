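{
  "pathway_id": "ko00195",
  "components": [
    {
      "name": "Photosystem II",
      "genes": {
        "psbA": "plastid", "psbB": "plastid", "psbC": "plastid",
        "psbD": "plastid", "psbE": "plastid", "psbF": "plastid",
        "psbH": "plastid", "psbI": "plastid", "psbJ": "plastid",
        "psbK": "plastid", "psbL": "plastid", "psbM": "plastid",
        "psbT": "plastid",
        "psbO": "nuclear", "psbP": "nuclear", "psbQ": "nuclear",
        "psbR": "nuclear", "psbS": "nuclear", "psbU": "nuclear",
        "psbV": "nuclear", "psbW": "nuclear", "psbX": "nuclear",
        "psbY": "nuclear", "psbTn": "nuclear",
        "psb27": "nuclear", "psb28": "nuclear", "psb28-2": "nuclear"
      }
    },
    {
      "name": "Photosystem I",
      "genes": {
        "psaA": "plastid", "psaB": "plastid", "psaC": "plastid",
        "psaI": "plastid", "psaJ": "plastid",
        "psaD": "nuclear", "psaE": "nuclear", "psaF": "nuclear",
        "psaG": "nuclear", "psaH": "nuclear", "psaK": "nuclear",
        "psaL": "nuclear", "psaN": "nuclear", "psaO": "nuclear",
        "psaP": "nuclear"
      }
    },
    {
      "name": "Cytochrome b6/f complex",
      "genes": {
        "petA": "plastid", "petG": "plastid", "petL": "plastid",
        "petN": "plastid",
        "petC": "nuclear", "petM": "nuclear"
      }
    },
    {
      "name": "Photosynthetic electron transport",
      "genes": {
        "petB": "plastid", "petD": "plastid",
        "petE": "nuclear", "petF": "nuclear", "petH": "nuclear",
        "petJ": "nuclear"
      }
    },
    {
      "name": "F-type ATPase",
      "genes": {
        "atpA": "plastid", "atpB": "plastid", "atpE": "plastid",
        "atpF": "plastid", "atpH": "plastid", "atpI": "plastid",
        "atpC": "nuclear", "atpD": "nuclear", "atpG": "nuclear"
      }
    }
  ],
  "aliases": {
    "alpha": "atpA",
    "beta": "atpB",
    "gamma": "atpC",
    "delta": "atpD",
    "epsilon": "atpE",
    "b": "atpF",
    "b'": "atpG",
    "c": "atpH",
    "a": "atpI"
  }
}
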