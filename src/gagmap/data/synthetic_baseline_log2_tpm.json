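{
 "comment": "Synthetic per-gene baseline log2(TPM) means for the expression simulators, drawn once from Uniform(0, 8) and frozen for reproducibility. Synthetic stand-in; not measured data.",
 "log2_tpm_mean": {
  "B3GALT6": 6.191648,
  "B3GAT3": 3.511028,
  "B3GNT7": 6.868783,
  "B4GALT4": 5.578944,
  "B4GALT7": 0.753419,
  "CANT1": 7.804979,
  "CHPF": 6.089118,
  "CHPF2": 6.288514,
  "CHST1": 1.024909,
  "CHST11": 3.603088,
  "CHST12": 2.966384,
  "CHST13": 7.41412,
  "CHST14": 5.150921,
  "CHST15": 6.582093,
  "CHST3": 3.547314,
  "CHST5": 1.81791,
  "CHST6": 4.436678,
  "CHSY1": 0.510538,
  "CHSY3": 6.621049,
  "CSGALNACT1": 5.053315,
  "CSGALNACT2": 6.064702,
  "DSE": 2.836208,
  "DSEL": 7.765584,
  "EXT1": 7.144969,
  "EXT2": 6.227068,
  "EXTL2": 1.55711,
  "EXTL3": 3.733768,
  "FAM20B": 0.35043,
  "GLCE": 1.234316,
  "GOLPH3": 5.464392,
  "HAS1": 5.958097,
  "HAS2": 7.740078,
  "HAS3": 2.606603,
  "HS2ST1": 2.963678,
  "HS3ST1": 3.756446,
  "HS3ST2": 1.515771,
  "HS3ST3A1": 1.039372,
  "HS3ST3B1": 3.805639,
  "HS3ST4": 1.815275,
  "HS3ST5": 5.358512,
  "HS3ST6": 3.497215,
  "HS6ST1": 6.661426,
  "HS6ST2": 5.602121,
  "HS6ST3": 2.498933,
  "HYAL1": 6.658078,
  "HYAL2": 6.438115,
  "IMPAD1": 3.099827,
  "KDM2B": 2.306625,
  "NDST1": 5.459964,
  "NDST2": 1.11802,
  "NDST3": 1.599266,
  "NDST4": 0.058898,
  "PAPSS1": 6.295395,
  "PAPSS2": 5.318807,
  "PXYLP1": 5.641323,
  "SLC35A2": 6.245832,
  "SLC35B2": 3.671326,
  "SLC35B3": 4.54993,
  "SLC35B4": 1.118376,
  "SPAM1": 0.916241,
  "SPPL3": 5.347224,
  "TMEM2": 3.76877,
  "UST": 4.521889,
  "XYLT1": 6.119991,
  "XYLT2": 5.077747,
  "ZNF263": 4.428635,
  "VCAN": 4.473657,
  "DCN": 2.431601,
  "BGN": 0.246543,
  "LUM": 3.493739,
  "SDC1": 1.716677,
  "ESM1": 3.268229,
  "ACAN": 6.827225,
  "HSPG2": 1.871516
 }
}
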