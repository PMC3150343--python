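{
  "description": "Published agreement counts between microarray-based (genomic, rows: G1/G3) and microscopic (histological, columns: G1/G2/G3) grading in five public breast-cancer cohorts. Counts transcribed from the published agreement table; used as worked-example inputs for the evaluate module.",
  "cohorts": {
    "Uppsala": {"n": 251, "G1": [63, 80, 4], "G3": [5, 48, 51]},
    "Stockholm": {"n": 147, "G1": [26, 44, 9], "G3": [2, 14, 52]},
    "Guys Hospital": {"n": 70, "G1": [16, 16, 0], "G3": [1, 21, 16]},
    "Oxford": {"n": 82, "G1": [15, 24, 1], "G3": [3, 26, 13]},
    "NKI": {"n": 295, "G1": [64, 68, 31], "G3": [11, 33, 88]}
  },
  "columns": ["G1", "G2", "G3"]
}
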