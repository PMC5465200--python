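{
  "comment": "ISOGG-2016-style placement of the 35 typed binary markers. Only typed levels are represented; parent=null means the node hangs directly off the Y root.",
  "nodes": [
    {"label": "C2-M217", "marker": "M217", "parent": null},
    {"label": "C2b1a2-M48", "marker": "M48", "parent": "M217"},
    {"label": "C2b1b-M128", "marker": "M128", "parent": "M217"},
    {"label": "D-M174", "marker": "M174", "parent": null},
    {"label": "E1b1b1-M35.1", "marker": "M35.1", "parent": null},
    {"label": "E1b1b1a1-M78", "marker": "M78", "parent": "M35.1"},
    {"label": "E1b1b1b2a-M123", "marker": "M123", "parent": "M35.1"},
    {"label": "G1-M285", "marker": "M285", "parent": null},
    {"label": "G2a-P15", "marker": "P15", "parent": null},
    {"label": "G2a2b2a-P303", "marker": "P303", "parent": "P15"},
    {"label": "G2a2b1-M406", "marker": "M406", "parent": "P15"},
    {"label": "H1-M69", "marker": "M69", "parent": null},
    {"label": "I-M170", "marker": "M170", "parent": null},
    {"label": "J1-M267", "marker": "M267", "parent": null},
    {"label": "J1a2b-P58", "marker": "P58", "parent": "M267"},
    {"label": "J2-M172", "marker": "M172", "parent": null},
    {"label": "J2a1a-M47", "marker": "M47", "parent": "M172"},
    {"label": "J2a1b-M67", "marker": "M67", "parent": "M172"},
    {"label": "J2a1b1-M92", "marker": "M92", "parent": "M67"},
    {"label": "J2b-M12", "marker": "M12", "parent": "M172"},
    {"label": "L-M20", "marker": "M20", "parent": null},
    {"label": "N1-LLY22g", "marker": "LLY22g", "parent": null},
    {"label": "N1c1-M178", "marker": "M178", "parent": "LLY22g"},
    {"label": "O1a-M119", "marker": "M119", "parent": null},
    {"label": "O1b-P31", "marker": "P31", "parent": null},
    {"label": "O2-M122", "marker": "M122", "parent": null},
    {"label": "O2a2-P201", "marker": "P201", "parent": "M122"},
    {"label": "O2a2b1-M134", "marker": "M134", "parent": "P201"},
    {"label": "Q-M242", "marker": "M242", "parent": null},
    {"label": "R1a1a-M198", "marker": "M198", "parent": null},
    {"label": "R1a1a1b1a1-M458", "marker": "M458", "parent": "M198"},
    {"label": "R1b-M343", "marker": "M343", "parent": null},
    {"label": "R1b1a1a2-M269", "marker": "M269", "parent": "M343"},
    {"label": "R2a-M124", "marker": "M124", "parent": null},
    {"label": "T1a-M70", "marker": "M70", "parent": null}
  ]
}
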