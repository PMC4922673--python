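{
  "comment": "Subgeneric standard banding sequences at section resolution. One token per numbered section, finer (section.subband) where a named rearrangement resolves inside a section: section 7 of IS carries a provisionally attributed band (7.2?), and section 85 of IIIL carries the two bands removed by the 85d deletion. Centromere-proximal ends follow the continuous section numbering of each chromosome (short arm runs distal-to-proximal, long arm proximal-to-distal).",
  "arms": {
    "IS": {
      "tokens": ["1", "2", "3", "4", "5", "6", "7.1", "7.2?", "8", "9", "10", "11", "12", "13", "14", "15", "16"],
      "landmarks": {"em": 0, "Ce": 16},
      "centromere_end": "right"
    },
    "IL": {
      "tokens": ["17", "18", "19", "20", "21", "22", "23", "24", "25", "26", "27", "28", "29", "30", "31", "32", "33", "34", "35", "36", "37", "38", "39"],
      "landmarks": {"Ce": 0, "Nk": 21},
      "centromere_end": "left"
    },
    "IIS": {
      "tokens": ["40", "41", "42", "43", "44", "45", "46", "47", "48", "49", "50", "51", "52", "53", "54", "55"],
      "landmarks": {"RoB": 1, "Ce": 15},
      "centromere_end": "right"
    },
    "IIL": {
      "tokens": ["56", "57", "58", "59", "60", "61", "62", "63", "64", "65", "66", "67", "68", "69", "70", "71", "72", "73", "74", "75"],
      "landmarks": {"Ce": 0, "Pb": 9},
      "centromere_end": "left"
    },
    "IIIS": {
      "tokens": ["76", "77", "78", "79", "80", "81", "82", "83"],
      "landmarks": {"bl": 0, "Ce": 7},
      "centromere_end": "right"
    },
    "IIIL": {
      "tokens": ["84", "85.1", "85.2", "86", "87", "88", "89", "90", "91", "92", "93", "94", "95", "96", "97", "98", "99", "100"],
      "landmarks": {"Ce": 0, "NO": 4},
      "centromere_end": "left"
    }
  }
}
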