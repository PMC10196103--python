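{
  "description": "Seven-class sellar-region segmentation schema for sagittal contrast-enhanced T1 MRI",
  "orientation": {
    "axis0": "left-right (sagittal slice stack)",
    "axis1": "posterior -> anterior (increasing index = more anterior)",
    "axis2": "inferior -> superior (increasing index = more superior)"
  },
  "default_spacing_mm": [6.0, 0.45, 0.45],
  "labels": {
    "0": {"name": "background", "note": "non-labeled component"},
    "1": {"name": "tumor", "note": "all tumor components incl. enhanced cyst walls and heterogeneous cysts"},
    "2": {"name": "pituitary", "note": "pituitary gland and stalk merged into one class"},
    "3": {"name": "sphenoid_sinus", "note": "air space plus bony wall / dura surrounding the pituitary fossa"},
    "4": {"name": "brain", "note": "cerebrum, cerebellum, brainstem"},
    "5": {"name": "suprasellar_cistern", "note": "suprasellar and interpeduncular cisterns; may be absent under tumor compression"},
    "6": {"name": "lateral_ventricle", "note": "lateral ventricles"}
  }
}
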