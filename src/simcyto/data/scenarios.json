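{
 "comment": "Canonical derivation scenarios per taxon and arm: ordered rearrangement steps from the subgeneric standard and the frozen resulting band order (signed labels; leading '-' marks a band in reversed orientation).",
 "scenarios": [
  {
   "taxon": "cholodkovskii",
   "arm": "IS",
   "sequence": "predominant",
   "start_label": "subgeneric standard",
   "steps": [
    "IS-17",
    "IS-18",
    "IS-19",
    "IS-20",
    "IS-21"
   ],
   "end_tokens": [
    "1",
    "-12",
    "-7.1",
    "-6",
    "-5",
    "-8",
    "-7.2",
    "-3",
    "9",
    "10",
    "11",
    "4",
    "-2",
    "13",
    "14",
    "15",
    "16"
   ],
   "n_fragments": 9
  },
  {
   "taxon": "cholodkovskii",
   "arm": "IL",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IL-1",
    "IL-17"
   ],
   "end_tokens": [
    "17",
    "18",
    "19",
    "-30",
    "-29",
    "-28",
    "-34",
    "-33",
    "-32",
    "-31",
    "20",
    "21",
    "22",
    "23",
    "24",
    "25",
    "26",
    "27",
    "35",
    "36",
    "37",
    "38",
    "39"
   ],
   "n_fragments": 5
  },
  {
   "taxon": "cholodkovskii",
   "arm": "IIS",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IIS-1",
    "IIS-4",
    "IIS-5",
    "IIS-6a"
   ],
   "end_tokens": [
    "40",
    "41",
    "50",
    "51",
    "-45",
    "-44",
    "49",
    "42",
    "43",
    "-48",
    "-47",
    "-46",
    "52",
    "53",
    "54",
    "55"
   ],
   "n_fragments": 7
  },
  {
   "taxon": "cholodkovskii",
   "arm": "IIL",
   "sequence": "predominant",
   "start_label": "subgeneric standard",
   "steps": [
    "IIL-1",
    "IIL-2",
    "IIL-16"
   ],
   "end_tokens": [
    "56",
    "-60",
    "-61",
    "57",
    "58",
    "59",
    "62",
    "-70",
    "-69",
    "-68",
    "-67",
    "-66",
    "-65",
    "-64",
    "-63",
    "71",
    "72",
    "73",
    "74",
    "75"
   ],
   "n_fragments": 6
  },
  {
   "taxon": "cholodkovskii",
   "arm": "IIIS",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IIIS-1"
   ],
   "end_tokens": [
    "76",
    "77",
    "-81",
    "-80",
    "-79",
    "-78",
    "82",
    "83"
   ],
   "n_fragments": 3
  },
  {
   "taxon": "cholodkovskii",
   "arm": "IIIL",
   "sequence": "predominant",
   "start_label": "subgeneric standard",
   "steps": [
    "IIIL-2",
    "IIIL-15",
    "IIIL-23",
    "IIIL-16"
   ],
   "end_tokens": [
    "84",
    "85.1",
    "85.2",
    "86",
    "-94",
    "92",
    "97",
    "98",
    "95",
    "96",
    "93",
    "-91",
    "-90",
    "-89",
    "-88",
    "-87",
    "99",
    "100"
   ],
   "n_fragments": 8
  },
  {
   "taxon": "decimatum",
   "arm": "IS",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IS-17",
    "IS-18",
    "IS-19"
   ],
   "end_tokens": [
    "1",
    "2",
    "-8",
    "-7.2",
    "-3",
    "9",
    "10",
    "11",
    "4",
    "5",
    "6",
    "7.1",
    "12",
    "13",
    "14",
    "15",
    "16"
   ],
   "n_fragments": 6
  },
  {
   "taxon": "decimatum",
   "arm": "IL",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IL-1",
    "IL-17"
   ],
   "end_tokens": [
    "17",
    "18",
    "19",
    "-30",
    "-29",
    "-28",
    "-34",
    "-33",
    "-32",
    "-31",
    "20",
    "21",
    "22",
    "23",
    "24",
    "25",
    "26",
    "27",
    "35",
    "36",
    "37",
    "38",
    "39"
   ],
   "n_fragments": 5
  },
  {
   "taxon": "decimatum",
   "arm": "IIS",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IIS-1",
    "IIS-4",
    "IIS-5",
    "IIS-6a"
   ],
   "end_tokens": [
    "40",
    "41",
    "50",
    "51",
    "-45",
    "-44",
    "49",
    "42",
    "43",
    "-48",
    "-47",
    "-46",
    "52",
    "53",
    "54",
    "55"
   ],
   "n_fragments": 7
  },
  {
   "taxon": "decimatum",
   "arm": "IIL",
   "sequence": "predominant",
   "start_label": "subgeneric standard",
   "steps": [
    "IIL-1",
    "IIL-2",
    "IIL-18"
   ],
   "end_tokens": [
    "56",
    "-60",
    "-61",
    "57",
    "58",
    "59",
    "-71",
    "-70",
    "-69",
    "-68",
    "-67",
    "-66",
    "-65",
    "-64",
    "-63",
    "-62",
    "72",
    "73",
    "74",
    "75"
   ],
   "n_fragments": 5
  },
  {
   "taxon": "decimatum",
   "arm": "IIIS",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IIIS-1"
   ],
   "end_tokens": [
    "76",
    "77",
    "-81",
    "-80",
    "-79",
    "-78",
    "82",
    "83"
   ],
   "n_fragments": 3
  },
  {
   "taxon": "decimatum",
   "arm": "IIIL",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IIIL-2",
    "IIIL-15",
    "IIIL-23"
   ],
   "end_tokens": [
    "84",
    "85.1",
    "85.2",
    "86",
    "-94",
    "-93",
    "-96",
    "-95",
    "-98",
    "-97",
    "-92",
    "-91",
    "-90",
    "-89",
    "-88",
    "-87",
    "99",
    "100"
   ],
   "n_fragments": 6
  },
  {
   "taxon": "nigricoxum",
   "arm": "IS",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IS-17",
    "IS-18",
    "IS-19"
   ],
   "end_tokens": [
    "1",
    "2",
    "-8",
    "-7.2",
    "-3",
    "9",
    "10",
    "11",
    "4",
    "5",
    "6",
    "7.1",
    "12",
    "13",
    "14",
    "15",
    "16"
   ],
   "n_fragments": 6
  },
  {
   "taxon": "nigricoxum",
   "arm": "IL",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IL-1",
    "IL-17",
    "IL-18"
   ],
   "end_tokens": [
    "17",
    "18",
    "19",
    "-30",
    "-29",
    "-28",
    "-34",
    "-33",
    "-32",
    "-25",
    "-24",
    "-23",
    "-22",
    "-21",
    "-20",
    "31",
    "26",
    "27",
    "35",
    "36",
    "37",
    "38",
    "39"
   ],
   "n_fragments": 7
  },
  {
   "taxon": "nigricoxum",
   "arm": "IIL",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IIL-1",
    "IIL-2"
   ],
   "end_tokens": [
    "56",
    "-60",
    "-61",
    "57",
    "58",
    "59",
    "62",
    "63",
    "64",
    "65",
    "66",
    "67",
    "68",
    "69",
    "70",
    "71",
    "72",
    "73",
    "74",
    "75"
   ],
   "n_fragments": 4
  },
  {
   "taxon": "nigricoxum",
   "arm": "IIS",
   "sequence": "X",
   "start_label": "subgeneric standard",
   "steps": [
    "IIS-1",
    "IIS-4",
    "IIS-5",
    "IIS-6a"
   ],
   "end_tokens": [
    "40",
    "41",
    "50",
    "51",
    "-45",
    "-44",
    "49",
    "42",
    "43",
    "-48",
    "-47",
    "-46",
    "52",
    "53",
    "54",
    "55"
   ],
   "n_fragments": 7
  },
  {
   "taxon": "nigricoxum",
   "arm": "IIS",
   "sequence": "Y",
   "start_label": "subgeneric standard",
   "steps": [
    "IIS-1",
    "IIS-5",
    "IIS-6a",
    "IIS-10"
   ],
   "end_tokens": [
    "40",
    "41",
    "50",
    "-43",
    "-42",
    "-49",
    "-48",
    "-47",
    "-51",
    "44",
    "45",
    "46",
    "52",
    "53",
    "54",
    "55"
   ],
   "n_fragments": 7
  },
  {
   "taxon": "nigricoxum",
   "arm": "IIIS",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IIIS-1"
   ],
   "end_tokens": [
    "76",
    "77",
    "-81",
    "-80",
    "-79",
    "-78",
    "82",
    "83"
   ],
   "n_fragments": 3
  },
  {
   "taxon": "nigricoxum",
   "arm": "IIIL",
   "sequence": "basic",
   "start_label": "subgeneric standard",
   "steps": [
    "IIIL-2",
    "IIIL-15",
    "IIIL-23"
   ],
   "end_tokens": [
    "84",
    "85.1",
    "85.2",
    "86",
    "-94",
    "-93",
    "-96",
    "-95",
    "-98",
    "-97",
    "-92",
    "-91",
    "-90",
    "-89",
    "-88",
    "-87",
    "99",
    "100"
   ],
   "n_fragments": 6
  }
 ]
}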