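{
  "known_target_site_counts": {
    "GSK3B": 43,
    "Cdk5": 13,
    "MAPK": 19,
    "DYRK1A": 3,
    "MARK4": 2,
    "Src": 1,
    "Fyn": 1,
    "c-Abl": 1,
    "ROCK": 3
  },
  "potential_site_composition": {
    "S": 45,
    "T": 35,
    "Y": 5,
    "total": 85
  },
  "transcribed_row_counts": {
    "CaMKII": 6,
    "Cdk5": 10,
    "GSK3B": 6,
    "MAPK": 2,
    "MARK4": 1,
    "CN": 5
  },
  "provenance": [
    "camkii-tau-sites: CaMKII target residues on Tau 2N4R",
    "cdk5-tau-sites: Cdk5 target residues on Tau 2N4R",
    "mark4-tau-sites: MARK4 target residues on Tau 2N4R",
    "cn-dephos-rates: calcineurin site-specific percent decreases in Tau phosphorylation",
    "tau-cambd-serines: AD-phosphorylated serines inside the Tau R2 CaMBD",
    "prephos-network: prephosphorylation relationships (kinase -> site, stage pre)",
    "hyperphos-network: hyperphosphorylation relationships (kinase -> site, stage hyper)"
  ]
}
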