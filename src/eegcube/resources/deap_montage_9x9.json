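{
  "version": 1,
  "description": "Canonical 9x9 grid placement of the 32 DEAP EEG channels (international 10-20 layout). Rows run anterior to posterior, columns left to right, midline in column 4; indices are 0-based. Channel order is the DEAP 'preprocessed Python' EEG channel order.",
  "grid_shape": [9, 9],
  "channel_order": [
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2"
  ],
  "assignments": {
    "Fp1": [0, 3],
    "Fp2": [0, 5],
    "AF3": [1, 3],
    "AF4": [1, 5],
    "F7": [2, 0],
    "F3": [2, 2],
    "Fz": [2, 4],
    "F4": [2, 6],
    "F8": [2, 8],
    "FC5": [3, 1],
    "FC1": [3, 3],
    "FC2": [3, 5],
    "FC6": [3, 7],
    "T7": [4, 0],
    "C3": [4, 2],
    "Cz": [4, 4],
    "C4": [4, 6],
    "T8": [4, 8],
    "CP5": [5, 1],
    "CP1": [5, 3],
    "CP2": [5, 5],
    "CP6": [5, 7],
    "P7": [6, 0],
    "P3": [6, 2],
    "Pz": [6, 4],
    "P4": [6, 6],
    "P8": [6, 8],
    "PO3": [7, 3],
    "PO4": [7, 5],
    "O1": [8, 3],
    "Oz": [8, 4],
    "O2": [8, 5]
  }
}
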