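{
  "_comment": "Per-compartment simulated-fluid make-up for each food class, as tabulated in the M.I.D.A. protocol. Enzyme target activities are U per ml of final compartment content (fluid mixed 50:50 with the incoming stream) unless basis says otherwise. version 1",
  "version": 1,
  "fluid_final_volume_ml": {"SSF": 45.0, "SGF": 80.0, "SIF": 80.0},
  "fluid_compartment": {"SSF": "oral", "SGF": "gastric", "SIF": "intestinal"},
  "fluid_target_pH": {"SSF": 7.0, "SGF": 3.0, "SIF": 7.0},
  "recipes": {
    "rice_starch": {
      "SSF": {
        "electrolyte_stock_total_ml": 31.5,
        "enzymes": [
          {"enzyme": "salivary alpha-amylase", "target_activity": 75.0,
           "activity_basis": "U/ml of oral content", "amount": 0.675, "amount_unit": "ml"}
        ],
        "cacl2_ml": 0.225, "hcl_1M_ml": 0.2, "nahco3_1M_ml": 0.0
      },
      "SGF": {
        "electrolyte_stock_total_ml": 60.0,
        "enzymes": [],
        "cacl2_ml": 0.04, "hcl_1M_ml": 0.22, "nahco3_1M_ml": 0.0
      },
      "SIF": {
        "electrolyte_stock_total_ml": 44.0,
        "enzymes": [
          {"enzyme": "pancreatic alpha-amylase", "target_activity": 170.5,
           "activity_basis": "U/ml of intestinal content", "amount": 2.73, "amount_unit": "ml"},
          {"enzyme": "glucoamylase", "target_activity": 18.755,
           "activity_basis": "U/ml of intestinal content", "amount": 2.308, "amount_unit": "g"}
        ],
        "cacl2_ml": 0.16, "hcl_1M_ml": 0.0, "nahco3_1M_ml": 0.0
      }
    },
    "rice_cream_basic": {
      "SSF": {
        "electrolyte_stock_total_ml": 31.5,
        "enzymes": [
          {"enzyme": "salivary alpha-amylase", "target_activity": 75.0,
           "activity_basis": "U/ml of oral content", "amount": 0.675, "amount_unit": "ml"}
        ],
        "cacl2_ml": 0.225, "hcl_1M_ml": 0.04, "nahco3_1M_ml": 0.0
      },
      "SGF": {
        "electrolyte_stock_total_ml": 60.0,
        "enzymes": [
          {"enzyme": "pepsin", "target_activity": 1000.0,
           "activity_basis": "U/ml of gastric content", "amount": 47.33, "amount_unit": "mg"}
        ],
        "cacl2_ml": 0.04, "hcl_1M_ml": 1.945, "nahco3_1M_ml": 0.0
      },
      "SIF": {
        "electrolyte_stock_total_ml": 44.0,
        "enzymes": [
          {"enzyme": "pancrelipase", "target_activity": 7695.0,
           "activity_basis": "lipase U total", "amount": 115.425, "amount_unit": "mg"},
          {"enzyme": "glucoamylase", "target_activity": 4.2323,
           "activity_basis": "U/ml of intestinal content", "amount": 0.52, "amount_unit": "g"}
        ],
        "cacl2_ml": 0.16, "hcl_1M_ml": 0.0, "nahco3_1M_ml": 0.18
      }
    },
    "rice_cream_premium": {
      "SSF": {
        "electrolyte_stock_total_ml": 31.5,
        "enzymes": [
          {"enzyme": "salivary alpha-amylase", "target_activity": 75.0,
           "activity_basis": "U/ml of oral content", "amount": 0.675, "amount_unit": "ml"}
        ],
        "cacl2_ml": 0.225, "hcl_1M_ml": 0.02, "nahco3_1M_ml": 0.0
      },
      "SGF": {
        "electrolyte_stock_total_ml": 60.0,
        "enzymes": [
          {"enzyme": "pepsin", "target_activity": 1000.0,
           "activity_basis": "U/ml of gastric content", "amount": 47.33, "amount_unit": "mg"}
        ],
        "cacl2_ml": 0.04, "hcl_1M_ml": 1.33, "nahco3_1M_ml": 0.0
      },
      "SIF": {
        "electrolyte_stock_total_ml": 44.0,
        "enzymes": [
          {"enzyme": "pancrelipase", "target_activity": 7695.0,
           "activity_basis": "lipase U total", "amount": 115.425, "amount_unit": "mg"},
          {"enzyme": "glucoamylase", "target_activity": 4.2323,
           "activity_basis": "U/ml of intestinal content", "amount": 0.52, "amount_unit": "g"}
        ],
        "cacl2_ml": 0.16, "hcl_1M_ml": 0.02, "nahco3_1M_ml": 0.02
      }
    }
  }
}
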