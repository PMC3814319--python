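{
  "HLA-A": {
    "peptide_BF": [5, 7, 9, 24, 25, 33, 34, 45, 63, 66, 67, 70, 77, 80, 81, 84, 95, 99, 114, 116, 123, 143, 146, 147, 159, 171],
    "TCR": [58, 59, 62, 65, 68, 69, 72, 75, 76, 79, 82, 145, 149, 150, 151, 154, 155, 157, 158, 162, 163, 166, 167, 170],
    "KIR": [17, 77, 79, 80, 81, 83, 84, 85, 86, 87, 88, 89, 90, 92, 142, 144, 145, 146, 151],
    "LILR": [192, 193, 194, 195, 196, 197, 198, 199, 200, 201, 202, 203, 207, 208, 212, 213, 214],
    "CD8": [223, 224, 225, 226, 227, 228, 229, 230, 231, 232, 233, 245]
  },
  "HLA-B": {
    "peptide_BF": [5, 7, 9, 24, 25, 33, 34, 45, 63, 66, 67, 70, 95, 97, 99, 114, 116, 123, 143, 146, 147, 159, 171],
    "TCR": [58, 59, 62, 65, 68, 69, 72, 75, 76, 149, 150, 151, 154, 155, 157, 158, 162, 163, 166, 167, 170],
    "KIR": [77, 78, 79, 80, 81, 82, 83, 84, 85, 86, 87, 88, 89, 90, 92, 142, 144, 145],
    "LILR": [192, 193, 194, 195, 196, 197, 198, 199, 200, 201, 202, 203, 207, 208, 212, 213, 214],
    "CD8": [223, 224, 225, 226, 227, 228, 229, 230, 231, 232, 233, 245]
  },
  "HLA-C": {
    "peptide_P2P9": [5, 7, 9, 14, 24, 25, 33, 34, 45, 49, 63, 66, 67, 70, 95, 97, 99, 114, 116, 123, 143, 146, 147, 159, 171],
    "TCR": [58, 59, 62, 65, 68, 69, 72, 75, 76, 149, 150, 151, 154, 155, 157, 158, 162, 163, 166, 167, 170],
    "KIR": [77, 78, 79, 80, 81, 82, 83, 84, 85, 86, 87, 88, 89, 90, 92, 142, 144, 145],
    "LILR": [192, 193, 194, 195, 196, 197, 198, 199, 200, 201, 202, 203, 207, 208, 212, 213, 214],
    "CD8": [223, 224, 225, 226, 227, 228, 229, 230, 231, 232, 233, 245],
    "alpha3_TM": [239, 253, 261, 273, 280, 297, 304, 311, 313, 320, 332, 339, 345]
  },
  "KIR3DL1": {
    "D0": [18, 20, 31, 44, 47, 51, 58, 86, 92],
    "D1D2_HLA_contact": [104, 105, 106, 125, 127, 158, 163, 165, 166, 199, 200, 201, 228, 230, 231, 277, 278, 279, 282, 283]
  },
  "KIR2DL1": {
    "HLA_contact": [44, 68, 70, 104, 105, 106, 131, 135, 154, 158, 163, 182, 183, 184],
    "stem_TM": [216, 233, 245]
  },
  "KIR2DL2": {
    "HLA_contact": [16, 44, 68, 70, 104, 105, 106, 131, 135, 154, 158, 163, 182, 183, 184]
  },
  "KIR3DL2": {
    "D0": [18, 20, 31, 44, 47, 51, 58, 86, 92]
  }
}
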