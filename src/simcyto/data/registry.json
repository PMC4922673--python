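{
  "comment": "Named rearrangements of the S. cholodkovskii lineage relative to the subgeneric standard. Inversion breakpoints are 0-based half-open inter-token positions in the arm coordinate frame at the step where the inversion enters the canonical derivation order; published maps resolve breakpoints only to within one or two fine bands, so positions here define the packaged reference geometry at section resolution. IS-18/IS-19 and IS-18/IS-21 each share one coincident breakpoint; IIS-6a and IIS-6b are the two alternative placements of the IIS-6 break that coincides with an IIS-1 breakpoint (6a is the default); IS-20 and IS-21 are absolutely linked, IS-21 nested inside IS-20.",
  "rearrangements": [
    {"name": "T(I;III)", "kind": "interchange",
     "pairing": [["IS", "IIIL"], ["IL", "IIIS"], ["IIS", "IIL"]],
     "centric_assignment": {"IS+IIIL": "III", "IL+IIIS": "I", "IIS+IIL": "II"},
     "status": "fixed_italic"},

    {"name": "IS-17", "kind": "inversion", "arm": "IS", "breakpoints": [2, 9], "status": "fixed_italic"},
    {"name": "IS-18", "kind": "inversion", "arm": "IS", "breakpoints": [4, 12], "status": "fixed_italic",
     "coincident_with": ["IS-19", "IS-21"]},
    {"name": "IS-19", "kind": "inversion", "arm": "IS", "breakpoints": [4, 8], "status": "fixed_italic",
     "coincident_with": ["IS-18"]},
    {"name": "IS-20", "kind": "inversion", "arm": "IS", "breakpoints": [1, 13], "linked_with": ["IS-21"]},
    {"name": "IS-21", "kind": "inversion", "arm": "IS", "breakpoints": [5, 12], "linked_with": ["IS-20"],
     "coincident_with": ["IS-18"]},
    {"name": "IS-22", "kind": "inversion", "arm": "IS", "breakpoints": [3, 7]},
    {"name": "IS-23", "kind": "inversion", "arm": "IS", "breakpoints": [6, 10]},
    {"name": "IS-24", "kind": "inversion", "arm": "IS", "breakpoints": [2, 6]},
    {"name": "IS-25", "kind": "inversion", "arm": "IS", "breakpoints": [8, 11]},
    {"name": "IS-26", "kind": "inversion", "arm": "IS", "breakpoints": [9, 14]},
    {"name": "IS-27", "kind": "inversion", "arm": "IS", "breakpoints": [2, 5]},
    {"name": "IS-28", "kind": "inversion", "arm": "IS", "breakpoints": [10, 13]},

    {"name": "IL-1", "kind": "inversion", "arm": "IL", "breakpoints": [3, 14], "status": "fixed_italic"},
    {"name": "IL-17", "kind": "inversion", "arm": "IL", "breakpoints": [6, 18], "status": "fixed_italic"},
    {"name": "IL-18", "kind": "inversion", "arm": "IL", "breakpoints": [9, 16], "status": "fixed_italic"},
    {"name": "IL-19", "kind": "inversion", "arm": "IL", "breakpoints": [2, 7]},
    {"name": "IL-20", "kind": "inversion", "arm": "IL", "breakpoints": [5, 11]},
    {"name": "IL-21", "kind": "inversion", "arm": "IL", "breakpoints": [12, 19]},
    {"name": "IL-22", "kind": "inversion", "arm": "IL", "breakpoints": [1, 6]},
    {"name": "IL-23", "kind": "inversion", "arm": "IL", "breakpoints": [8, 15]},
    {"name": "IL-24", "kind": "inversion", "arm": "IL", "breakpoints": [10, 20]},
    {"name": "IL-25", "kind": "inversion", "arm": "IL", "breakpoints": [4, 9]},
    {"name": "IL-26", "kind": "inversion", "arm": "IL", "breakpoints": [13, 21]},
    {"name": "IL-27", "kind": "inversion", "arm": "IL", "breakpoints": [7, 12]},
    {"name": "IL-28", "kind": "inversion", "arm": "IL", "breakpoints": [15, 22]},

    {"name": "IIS-1", "kind": "inversion", "arm": "IIS", "breakpoints": [2, 10], "status": "fixed_italic",
     "coincident_with": ["IIS-6a", "IIS-6b"]},
    {"name": "IIS-4", "kind": "inversion", "arm": "IIS", "breakpoints": [3, 8]},
    {"name": "IIS-5", "kind": "inversion", "arm": "IIS", "breakpoints": [5, 12], "status": "fixed_italic"},
    {"name": "IIS-6a", "kind": "inversion", "arm": "IIS", "breakpoints": [2, 7], "status": "fixed_italic",
     "coincident_with": ["IIS-1"], "mutually_exclusive_with": ["IIS-6b"]},
    {"name": "IIS-6b", "kind": "inversion", "arm": "IIS", "breakpoints": [7, 10], "status": "fixed_italic",
     "coincident_with": ["IIS-1"], "mutually_exclusive_with": ["IIS-6a"]},
    {"name": "IIS-7", "kind": "inversion", "arm": "IIS", "breakpoints": [4, 11]},
    {"name": "IIS-8", "kind": "inversion", "arm": "IIS", "breakpoints": [1, 6]},
    {"name": "IIS-9", "kind": "inversion", "arm": "IIS", "breakpoints": [9, 14]},
    {"name": "IIS-10", "kind": "inversion", "arm": "IIS", "breakpoints": [3, 9]},
    {"name": "IIS-11", "kind": "inversion", "arm": "IIS", "breakpoints": [6, 13]},
    {"name": "IIS 43Hb", "kind": "heteroband", "arm": "IIS", "section": 43},

    {"name": "IIL-1", "kind": "inversion", "arm": "IIL", "breakpoints": [1, 5], "status": "fixed_italic"},
    {"name": "IIL-2", "kind": "inversion", "arm": "IIL", "breakpoints": [2, 6], "status": "fixed_italic"},
    {"name": "IIL-16", "kind": "inversion", "arm": "IIL", "breakpoints": [7, 15]},
    {"name": "IIL-17", "kind": "inversion", "arm": "IIL", "breakpoints": [8, 14]},
    {"name": "IIL-18", "kind": "inversion", "arm": "IIL", "breakpoints": [6, 16]},
    {"name": "IIL 69Hb", "kind": "heteroband", "arm": "IIL", "section": 69},

    {"name": "IIIS-1", "kind": "inversion", "arm": "IIIS", "breakpoints": [2, 6], "status": "fixed_italic"},
    {"name": "IIIS-3", "kind": "inversion", "arm": "IIIS", "breakpoints": [3, 7]},

    {"name": "IIIL-2", "kind": "inversion", "arm": "IIIL", "breakpoints": [4, 12], "status": "fixed_italic"},
    {"name": "IIIL-15", "kind": "inversion", "arm": "IIIL", "breakpoints": [6, 14], "status": "fixed_italic"},
    {"name": "IIIL-16", "kind": "inversion", "arm": "IIIL", "breakpoints": [5, 11]},
    {"name": "IIIL-17", "kind": "inversion", "arm": "IIIL", "breakpoints": [2, 9]},
    {"name": "IIIL-18", "kind": "inversion", "arm": "IIIL", "breakpoints": [10, 17]},
    {"name": "IIIL-19", "kind": "inversion", "arm": "IIIL", "breakpoints": [3, 8]},
    {"name": "IIIL-20", "kind": "inversion", "arm": "IIIL", "breakpoints": [7, 13]},
    {"name": "IIIL-21", "kind": "inversion", "arm": "IIIL", "breakpoints": [1, 6]},
    {"name": "IIIL-22", "kind": "inversion", "arm": "IIIL", "breakpoints": [9, 15]},
    {"name": "IIIL-23", "kind": "inversion", "arm": "IIIL", "breakpoints": [8, 16], "status": "fixed_italic"},
    {"name": "IIIL-24", "kind": "inversion", "arm": "IIIL", "breakpoints": [12, 18]},
    {"name": "IIIL-25", "kind": "inversion", "arm": "IIIL", "breakpoints": [2, 10]},
    {"name": "IIIL 85d", "kind": "deletion", "arm": "IIIL", "section": 85, "band_count": 2},
    {"name": "IIIL repattern", "kind": "unresolved_repattern", "arm": "IIIL"}
  ]
}
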