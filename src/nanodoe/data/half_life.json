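{
  "_comment": "N-end-rule estimated half-life by N-terminal residue: [mammalian reticulocytes in vitro, yeast in vivo, E. coli in vivo]",
  "A": ["4.4 h", ">20 h", ">10 h"],
  "R": ["1 h", "2 min", "2 min"],
  "N": ["1.4 h", "3 min", ">10 h"],
  "D": ["1.1 h", "3 min", ">10 h"],
  "C": ["1.2 h", ">20 h", ">10 h"],
  "Q": ["0.8 h", "10 min", ">10 h"],
  "E": ["1 h", "30 min", ">10 h"],
  "G": ["30 h", ">20 h", ">10 h"],
  "H": ["3.5 h", "10 min", ">10 h"],
  "I": ["20 h", "30 min", ">10 h"],
  "L": ["5.5 h", "3 min", "2 min"],
  "K": ["1.3 h", "3 min", "2 min"],
  "M": ["30 h", ">20 h", ">10 h"],
  "F": ["1.1 h", "3 min", "2 min"],
  "P": [">20 h", ">20 h", "?"],
  "S": ["1.9 h", ">20 h", ">10 h"],
  "T": ["7.2 h", ">20 h", ">10 h"],
  "W": ["2.8 h", "3 min", "2 min"],
  "Y": ["2.8 h", "10 min", "2 min"],
  "V": ["100 h", ">20 h", ">10 h"]
}
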