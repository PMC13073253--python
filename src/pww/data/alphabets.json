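{
  "a12": {
    "description": "12-class physicochemical grouping; positively charged R and K share symbol 'b'",
    "mapping": {
      "A": "a", "G": "a",
      "R": "b", "K": "b",
      "D": "c", "E": "c",
      "N": "d", "Q": "d",
      "C": "e",
      "H": "f",
      "I": "g", "L": "g", "V": "g",
      "F": "h", "Y": "h",
      "M": "i",
      "P": "j",
      "S": "k", "T": "k",
      "W": "m"
    }
  },
  "a4": {
    "description": "4-class grouping: hydrophobic / polar / positive / negative",
    "mapping": {
      "A": "h", "C": "h", "F": "h", "G": "h", "I": "h",
      "L": "h", "M": "h", "P": "h", "V": "h", "W": "h",
      "N": "p", "Q": "p", "S": "p", "T": "p", "Y": "p", "H": "p",
      "K": "b", "R": "b",
      "D": "c", "E": "c"
    }
  }
}
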