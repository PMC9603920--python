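{
  "comment": "synthetic example of the MN ROI polygon format: one closed polygon per motor neuron, vertices as [row, col] pixel coordinates",
  "rois": [
    {"mn_id": 1, "vertices": [[10, 10], [10, 40], [40, 40], [40, 10]]},
    {"mn_id": 2, "vertices": [[60, 20], [55, 45], [75, 55], [85, 30]]},
    {"mn_id": 3, "vertices": [[20, 70], [15, 95], [45, 95], [40, 65]]}
  ]
}
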