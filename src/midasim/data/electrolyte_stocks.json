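{
  "_comment": "Electrolyte stock solutions for the simulated digestive fluids (INFOGEST-style), volumes in ml per 400 ml of stock solution. version 1",
  "version": 1,
  "stock_volume_ml": 400.0,
  "stocks": {
    "SSF": {
      "target_pH": 7.0,
      "components_ml": {
        "KCl 0.5 M": 15.1,
        "KH2PO4 0.5 M": 3.7,
        "NaHCO3 1 M": 6.8,
        "NaCl 2 M": 0.0,
        "MgCl2(H2O)6 0.15 M": 0.5,
        "(NH4)2CO3 0.5 M": 0.06,
        "HCl 6 M": 0.49,
        "H2O": 373.35
      }
    },
    "SGF": {
      "target_pH": 3.0,
      "components_ml": {
        "KCl 0.5 M": 6.9,
        "KH2PO4 0.5 M": 0.9,
        "NaHCO3 1 M": 7.2,
        "NaCl 2 M": 11.8,
        "MgCl2(H2O)6 0.15 M": 0.4,
        "(NH4)2CO3 0.5 M": 0.5,
        "HCl 6 M": 1.3,
        "H2O": 371.0
      }
    },
    "SIF": {
      "target_pH": 7.0,
      "components_ml": {
        "KCl 0.5 M": 6.8,
        "KH2PO4 0.5 M": 0.8,
        "NaHCO3 1 M": 5.26,
        "NaCl 2 M": 9.6,
        "MgCl2(H2O)6 0.15 M": 1.1,
        "(NH4)2CO3 0.5 M": 0.0,
        "HCl 6 M": 0.7,
        "H2O": 375.74
      }
    }
  }
}
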