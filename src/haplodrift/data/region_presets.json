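{
  "noncoding": {
    "name": "noncoding",
    "included_intervals": [[1, 576], [16024, 16569]],
    "excluded_positions": [303, 304, 305, 306, 307, 308, 309, 310, 311, 312, 313, 314, 315,
                           522, 523,
                           16180, 16181, 16182, 16183, 16184, 16185, 16186, 16187, 16188,
                           16189, 16190, 16191, 16192, 16193,
                           16519]
  },
  "coding": {
    "name": "coding",
    "_comment": "Union of the 13 rCRS protein-coding gene intervals (ND1 3307-4262, ND2 4470-5511, COX1 5904-7445, COX2 7586-8269, ATP8 8366-8572, ATP6 8527-9207, COX3 9207-9990, ND3 10059-10404, ND4L 10470-10766, ND4 10760-12137, ND5 12337-14148, ND6 14149-14673, CYB 14747-15887); overlaps merged, 11341 positions.",
    "included_intervals": [[3307, 4262], [4470, 5511], [5904, 7445], [7586, 8269],
                           [8366, 9990], [10059, 10404], [10470, 12137],
                           [12337, 14673], [14747, 15887]],
    "excluded_positions": []
  },
  "full": {
    "name": "full",
    "included_intervals": [[1, 16569]],
    "excluded_positions": []
  }
}
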