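{
  "schema_version": 1,
  "hybrid_node": "CD8086",
  "core_nodes": [
    "CD8086", "AMPK", "TCR", "CD28", "CD25", "IL2G", "MTOR", "CTLA4",
    "CTLA4dim", "NDRG1", "MTORC1", "MTORC2", "AP1", "STAT5", "NFAT", "NFKB",
    "AKT", "BCL2", "DAG", "SOS", "RASGTPR", "PDK1", "LCK", "ZAP70", "LAT",
    "PLC", "PIP2", "IP3", "Ca", "PKCT"
  ],
  "input_nodes": ["CD8086", "AMPK", "IL12e", "IFNGe", "IL4e", "TGFBe", "IL10e", "IL21e"],
  "activation_markers": ["IL2G", "AP1", "NFAT", "NFKB"],
  "phenotype_markers": {
    "Th1": ["TBET", "IFNG"],
    "Th2": ["GATA3", "IL4"],
    "Th17": ["RORGT", "IL21"],
    "Treg": ["FOXP3", "IL10", "TGFB"]
  },
  "scenarios": {
    "activation": {
      "inputs": {"CD8086": 1, "AMPK": 0},
      "init_active": ["TCR"],
      "expected_class": "activation"
    },
    "anergy_no_cd28": {
      "inputs": {"CD8086": 0, "AMPK": 0},
      "init_active": ["TCR"],
      "expected_class": "anergy_no_cd28"
    },
    "ndrg1_overexpression": {
      "inputs": {"CD8086": 1, "AMPK": 0},
      "init_active": ["TCR"],
      "clamp": {"NDRG1": 1},
      "expected_class": "anergy_no_cd28"
    },
    "checkpoint": {
      "inputs": {"AMPK": 0},
      "init_active": ["TCR"],
      "hybrid": true,
      "expected_class": "checkpoint"
    },
    "th1": {
      "inputs": {"CD8086": 1, "AMPK": 0, "IL12e": 1, "IFNGe": 1},
      "init_active": ["TCR"],
      "expected_class": "Th1"
    },
    "th2": {
      "inputs": {"CD8086": 1, "AMPK": 1, "IL4e": 1},
      "init_active": ["TCR"],
      "expected_class": "Th2"
    },
    "th17": {
      "inputs": {"CD8086": 1, "AMPK": 0, "IL12e": 1, "TGFBe": 1, "IL21e": 1},
      "init_active": ["TCR"],
      "expected_class": "Th17"
    },
    "treg": {
      "inputs": {"CD8086": 1, "AMPK": 1, "TGFBe": 1, "IL10e": 1},
      "init_active": ["TCR"],
      "expected_class": "Treg"
    }
  }
}
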