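{
  "comment": "Published model-based results for the two lineup-size studies, at the source's reporting precision (parameters and G2 to 2 decimals, p to 3). Used by the `replicate` command to diff freshly computed fits against the published record.",
  "exp1": {
    "base": {"g_squared": 8.39, "df": 6, "p_value": 0.211, "b": 0.07, "se_b": 0.01, "dA": 0.11, "se_dA": 0.02},
    "contrasts": {
      "size_dP": {"delta_g_squared": 22.17, "delta_df": 2},
      "size_g": {"delta_g_squared": 10.86, "delta_df": 2, "p_value": 0.004},
      "format_dP": {"delta_g_squared": 5.47, "delta_df": 2, "p_value": 0.065},
      "format_g": {"delta_g_squared": 209.42, "delta_df": 2}
    },
    "sensitivity": {"n_participants": 1537, "decisions_per_participant": 4, "df": 2, "alpha": 0.05, "power": 0.95, "minimal_w": 0.05}
  },
  "exp2": {
    "base": {"g_squared": 12.14, "df": 6, "p_value": 0.059, "b": 0.10, "se_b": 0.01, "dA": 0.11, "se_dA": 0.02},
    "contrasts": {
      "size_dP": {"delta_g_squared": 38.72, "delta_df": 2},
      "size_g": {"delta_g_squared": 62.98, "delta_df": 2},
      "format_dP": {"delta_g_squared": 3.24, "delta_df": 2, "p_value": 0.198},
      "format_g": {"delta_g_squared": 210.16, "delta_df": 2}
    },
    "sensitivity": {"n_participants": 1596, "decisions_per_participant": 4, "df": 2, "alpha": 0.05, "power": 0.95, "minimal_w": 0.05}
  }
}
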