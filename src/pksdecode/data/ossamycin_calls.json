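{
  "description": "Domain-call fixture for the eight ossamycin PKS multienzymes (OssA1-A8), transcribed from the published module-by-module active-site analysis. Each domain lists its fingerprint motifs; classification is recomputed from these motifs at load time, never stored. Proteins appear in cluster-table order, NOT assembly-line order. Labels name the chain-extension cycle(s) each module serves in the established line and are informative only.",
  "proteins": [
    {
      "protein_id": "OssA5",
      "domains": [
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 9/10"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSQ", "AT_second_his_motif": "HAFH"}},
        {"type": "DH", "motifs": {"DH_his_motif": "HELLGGRSLPG", "DH_asp_motif": "DAAFQ"}},
        {"type": "ER", "motifs": {"ER_tyr_motif": "GVKAL"}},
        {"type": "KR", "motifs": {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y", "KR_LDD_motif": "LNA", "KR_A_trp": "W", "KR_A2_his_for_gln": "Q"}},
        {"type": "ACP"}
      ]
    },
    {
      "protein_id": "OssA6",
      "domains": [
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 11"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSI", "AT_second_his_motif": "YASH"}},
        {"type": "DH", "motifs": {"DH_his_motif": "HELLGGRSLPG", "DH_asp_motif": "DAAFQ"}},
        {"type": "ER", "motifs": {"ER_tyr_motif": "GYKAL"}},
        {"type": "KR", "motifs": {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y", "KR_LDD_motif": "LNA", "KR_A_trp": "W", "KR_A2_his_for_gln": "Q"}},
        {"type": "ACP"}
      ]
    },
    {
      "protein_id": "OssA1",
      "domains": [
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTAQSSS"}, "label": "loading"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSI", "AT_second_his_motif": "YASH"}},
        {"type": "ACP"},
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 1"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSI", "AT_second_his_motif": "YASH"}},
        {"type": "DH", "motifs": {"DH_his_motif": "RELLGGRSLPG", "DH_asp_motif": "DAAFQ"}},
        {"type": "KR", "motifs": {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y", "KR_LDD_motif": "LDD", "KR_A_trp": "F", "KR_A2_his_for_gln": "Q"}},
        {"type": "ACP"},
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 2"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSL", "AT_second_his_motif": "YASH"}},
        {"type": "KR", "motifs": {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y", "KR_LDD_motif": "LNA", "KR_A_trp": "W", "KR_A2_his_for_gln": "Q"}},
        {"type": "ACP"}
      ]
    },
    {
      "protein_id": "OssA2",
      "domains": [
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 3"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSQ", "AT_second_his_motif": "HAFH"}},
        {"type": "DH", "motifs": {"DH_his_motif": "HELLGGRSLPG", "DH_asp_motif": "DAAFQ"}},
        {"type": "ER", "motifs": {"ER_tyr_motif": "GVKAL"}},
        {"type": "KR", "motifs": {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y", "KR_LDD_motif": "LNA", "KR_A_trp": "W", "KR_A2_his_for_gln": "Q"}},
        {"type": "ACP"},
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 4"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSV", "AT_second_his_motif": "YASH"}},
        {"type": "ACP"},
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 5"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSQ", "AT_second_his_motif": "HAFH"}},
        {"type": "KR", "motifs": {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y", "KR_LDD_motif": "LDD", "KR_A_trp": "F", "KR_A2_his_for_gln": "Q"}},
        {"type": "ACP"}
      ]
    },
    {
      "protein_id": "OssA3",
      "domains": [
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 6"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSI", "AT_second_his_motif": "YASH"}},
        {"type": "KR", "motifs": {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y", "KR_LDD_motif": "LNA", "KR_A_trp": "W", "KR_A2_his_for_gln": "Q"}},
        {"type": "ACP"},
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 7"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSV", "AT_second_his_motif": "SPGH"}},
        {"type": "DH", "motifs": {"DH_his_motif": "YELLGGRSLPG", "DH_asp_motif": "DAAFQ"}},
        {"type": "ACP"}
      ]
    },
    {
      "protein_id": "OssA4",
      "domains": [
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 8"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSL", "AT_second_his_motif": "YASH"}},
        {"type": "DH", "motifs": {"DH_his_motif": "HELLGGRSLPG", "DH_asp_motif": "DAAFQ"}},
        {"type": "ER", "motifs": {"ER_tyr_motif": "GVKAL"}},
        {"type": "KR", "motifs": {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y", "KR_LDD_motif": "LNA", "KR_A_trp": "W", "KR_A2_his_for_gln": "Q"}},
        {"type": "ACP"}
      ]
    },
    {
      "protein_id": "OssA7",
      "domains": [
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 12"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSQ", "AT_second_his_motif": "HAFH"}},
        {"type": "DH", "motifs": {"DH_his_motif": "HELLGGRSLPG", "DH_asp_motif": "DAAFQ"}},
        {"type": "ER", "motifs": {"ER_tyr_motif": "GVKAL"}},
        {"type": "KR", "motifs": {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y", "KR_LDD_motif": "LNA", "KR_A_trp": "W", "KR_A2_his_for_gln": "Q"}},
        {"type": "ACP"},
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 13"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSI", "AT_second_his_motif": "YASH"}},
        {"type": "DH", "motifs": {"DH_his_motif": "HELLGGRSLPG", "DH_asp_motif": "DAAFQ"}},
        {"type": "ER", "motifs": {"ER_tyr_motif": "GVKAL"}},
        {"type": "KR", "motifs": {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y", "KR_LDD_motif": "LDD", "KR_A_trp": "F", "KR_A2_his_for_gln": "Q"}},
        {"type": "ACP"}
      ]
    },
    {
      "protein_id": "OssA8",
      "domains": [
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 14"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSQ", "AT_second_his_motif": "HAFH"}},
        {"type": "DH", "motifs": {"DH_his_motif": "HELLGGRSLPG", "DH_asp_motif": "DAAFQ"}},
        {"type": "ER", "motifs": {"ER_tyr_motif": "GVKAL"}},
        {"type": "KR", "motifs": {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y", "KR_LDD_motif": "LNA", "KR_A_trp": "W", "KR_A2_his_for_gln": "Q"}},
        {"type": "ACP"},
        {"type": "KS", "motifs": {"KS_Q_substitution": "VDTACSSS"}, "label": "module 15"},
        {"type": "AT", "motifs": {"AT_serine_motif": "GHSQ", "AT_second_his_motif": "HAFH"}},
        {"type": "DH", "motifs": {"DH_his_motif": "HELLGGRSLPG", "DH_asp_motif": "DAAFQ"}},
        {"type": "KR", "motifs": {"KR_lys": "K", "KR_ser": "S", "KR_tyr": "Y", "KR_LDD_motif": "LNA", "KR_A_trp": "W", "KR_A2_his_for_gln": "Q"}},
        {"type": "ACP"},
        {"type": "TE"}
      ]
    }
  ]
}
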