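{
  "name": "human",
  "note": "Relative synonymous codon usage fractions for Homo sapiens (approximate standard values; normalized per amino acid on load).",
  "usage": {
    "A": {"GCT": 0.27, "GCC": 0.40, "GCA": 0.23, "GCG": 0.11},
    "R": {"CGT": 0.08, "CGC": 0.18, "CGA": 0.11, "CGG": 0.20, "AGA": 0.21, "AGG": 0.21},
    "N": {"AAT": 0.47, "AAC": 0.53},
    "D": {"GAT": 0.46, "GAC": 0.54},
    "C": {"TGT": 0.46, "TGC": 0.54},
    "Q": {"CAA": 0.27, "CAG": 0.73},
    "E": {"GAA": 0.42, "GAG": 0.58},
    "G": {"GGT": 0.16, "GGC": 0.34, "GGA": 0.25, "GGG": 0.25},
    "H": {"CAT": 0.42, "CAC": 0.58},
    "I": {"ATT": 0.36, "ATC": 0.47, "ATA": 0.17},
    "L": {"TTA": 0.08, "TTG": 0.13, "CTT": 0.13, "CTC": 0.20, "CTA": 0.07, "CTG": 0.40},
    "K": {"AAA": 0.43, "AAG": 0.57},
    "M": {"ATG": 1.0},
    "F": {"TTT": 0.46, "TTC": 0.54},
    "P": {"CCT": 0.29, "CCC": 0.32, "CCA": 0.28, "CCG": 0.11},
    "S": {"TCT": 0.19, "TCC": 0.22, "TCA": 0.15, "TCG": 0.05, "AGT": 0.15, "AGC": 0.24},
    "T": {"ACT": 0.25, "ACC": 0.36, "ACA": 0.28, "ACG": 0.11},
    "W": {"TGG": 1.0},
    "Y": {"TAT": 0.44, "TAC": 0.56},
    "V": {"GTT": 0.18, "GTC": 0.24, "GTA": 0.12, "GTG": 0.46}
  }
}
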