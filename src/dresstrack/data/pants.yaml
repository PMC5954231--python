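# Pants marker layout: region -> fiducial marker IDs.
garment: pants
regions:
  pants_back: [22]
  pants_inside_front: [17]
  pants_inside_back: [19]
  pants_low_left: [28, 29]
  pants_low_right: [25, 26]
  pants_upper_front: [15, 16, 24, 27]
velcro_pairs: []
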