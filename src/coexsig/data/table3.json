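{
  "description": "Stage-wise differentially expressed transcripts for the five staging-and-survival (SAS) co-expression modules of the TCGA-LUAD network, with hub status (top 10% module membership by kME) and the module-level regulation direction between stage 1 and later stages.",
  "modules": {
    "M1": {
      "color": "turquoise",
      "direction": "down",
      "stage1_vs_2": ["hsa-mir-3189", "hsa-let-7D", "hsa-mir-25", "LINC00342", "LINC00685", "hsa-mir-186", "hsa-mir-3682", "CLUHP3"],
      "hubs_stage1_vs_2": [],
      "stage1_vs_rest": ["hsa-mir-3189", "NPIPB15", "ZDHHC11B", "hsa-let-7D", "LINC00342", "CLUHP3", "LINC00685", "hsa-mir-3682"],
      "hubs_stage1_vs_rest": []
    },
    "M3": {
      "color": "brown",
      "direction": "up",
      "stage1_vs_2": ["FAM83A", "MYBL2", "KIF4A", "STC1", "RRM2", "DEPDC1", "ANLN"],
      "hubs_stage1_vs_2": ["MYBL2", "KIF4A", "RRM2", "DEPDC1", "ANLN"],
      "stage1_vs_rest": ["FAM83A", "STC1", "ANLN", "ELOVL6", "LYPD3", "RRM2", "SLC2A1", "MYBL2", "KIF4A", "CEP55", "TNNT1", "EXO1", "TUBB3", "HMMR", "DEPDC1", "MKI67", "FOXM1"],
      "hubs_stage1_vs_rest": ["ANLN", "RRM2", "MYBL2", "KIF4A", "CEP55", "EXO1", "HMMR", "DEPDC1", "FOXM1"]
    },
    "M6": {
      "color": "red",
      "direction": "down",
      "stage1_vs_2": ["SCGB3A2", "CYP4B1", "CRYM", "PIGR", "WIF1", "C4BPA", "CYP2B7P", "SFTPB", "VSIG2", "PRSS12", "PLA2G10", "CACNA2D2", "ELAPOR1", "DUOXA1", "ZBTB7C", "ALPL", "CLIC6", "HLF", "FAM189A2", "CYP4X1", "DUOX1", "CFAP221", "C5orf49", "CEBPA-DT", "B3GNT8", "ENTPD3", "SCUBE2", "OLFM1", "ERICH2", "WFDC2", "PDZD2"],
      "hubs_stage1_vs_2": ["SCGB3A2", "CYP4B1", "CYP2B7P", "SFTPB", "CACNA2D2", "HLF", "FAM189A2", "CFAP221", "B3GNT8"],
      "stage1_vs_rest": ["PGC", "SFTPC", "SCGB3A2", "CYP4B1", "CRYM", "CYP2B7P", "AQP5", "SCGB3A1", "PIGR", "C4BPA", "SFTPB", "C16orf89", "CLDN18", "SFTPA2", "DMBT1", "CACNA2D2", "WIF1", "PRSS12", "GGTLC1", "SFTPA1", "VSIG2", "AQP4", "SCGB1A1", "TMEM130", "HLF", "LRRK2-DT", "SFTPD", "C8orf34-AS1", "ATP13A4", "AGER", "FAM189A2", "ALPL", "ELAPOR1", "SUSD2", "CLIC6", "RNASE1", "CFAP221", "CYP4X1", "PLA2G10", "NAPSA", "PEBP4", "SFTA3", "CEBPA-DT", "GGT6", "HSD17B6", "LMO3", "IRX2", "TDRD10", "B3GNT8", "SCTR", "SPINK5", "ESYT3", "PLA2G1B", "HABP2", "SCUBE2", "C5orf49", "CFTR", "WFDC2", "GFRA3", "DAPK2", "MFSD4A", "ZBTB7C", "CPAMD8", "FCGBP", "ZNF750", "KLF15", "SUSD4"],
      "hubs_stage1_vs_rest": ["SCGB3A2", "CYP4B1", "CYP2B7P", "C16orf89", "CACNA2D2", "GGTLC1", "HLF", "LRRK2-DT", "ATP13A4", "SUSD2", "CFAP221", "NAPSA", "PEBP4", "SFTA3", "B3GNT8", "SCTR", "ESYT3", "DAPK2", "CPAMD8"]
    },
    "M9": {
      "color": "magenta",
      "direction": "down",
      "stage1_vs_2": ["FDCSP", "MS4A1", "PTGDS", "RAB37"],
      "hubs_stage1_vs_2": [],
      "stage1_vs_rest": ["FDCSP", "MS4A1", "PTGDS", "hsa-mir-8071-1"],
      "hubs_stage1_vs_rest": []
    },
    "M16": {
      "color": "lightcyan",
      "direction": null,
      "stage1_vs_2": [],
      "hubs_stage1_vs_2": [],
      "stage1_vs_rest": ["CD19", "CD79A", "CR2", "IGHJ3P", "IGHV3-63", "IGLV10-54", "IGHD", "IGHM", "IGHJ1", "IGHV3-47", "IGLC3", "IGKV6D-21", "IGKV1D-16", "IGLV1-44", "IGLC7", "IGLV2-18", "IGHV3-13", "IGKV1-8", "IGHV3-64", "IGLV3-9", "IGLV1-36", "IGLV3-27", "IGLV8-61"],
      "hubs_stage1_vs_rest": []
    }
  }
}
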