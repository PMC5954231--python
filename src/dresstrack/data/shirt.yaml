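# Shirt marker layout: region -> fiducial marker IDs.
garment: shirt
regions:
  shirt_front: [5, 6, 10, 11, 12, 13, 14, 30, 31, 32, 33, 34, 208, 209, 211, 212]
  shirt_back: [7]
  shirt_inside_center: [8]
  shirt_inside_side: [9]
  shirt_front_right: [5, 10, 11, 12, 13, 14, 208, 211]
  shirt_front_left: [6, 30, 31, 32, 33, 34, 209, 212]
  shirt_velcro: [208, 209, 211, 212]
velcro_pairs:
  - [208, 209]
  - [211, 212]
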