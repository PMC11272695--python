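{
  "version": "htpbk-reference-adult-male-1.0",
  "description": "Healthy adult male reference physiology compiled from published reference-man organ weight and regional blood-flow tables. Volumes in L, flows in L/h. Liver blood_flow is the hepatic-artery contribution only; gut and spleen outflow drains through the liver (portal route). Lung flow equals cardiac output.",
  "body_weight_kg": 73.0,
  "body_density_g_per_ml": 1.05,
  "gfr_L_per_h": 7.5,
  "hepatocellularity_cells_per_g": 110000000.0,
  "liver_density_g_per_ml": 1.05,
  "demographics": {"sex": "male", "age_y": 30, "height_cm": 176, "weight_kg": 73.0},
  "cardiac_output_L_per_h": 390.0,
  "organs": [
    {"name": "lung",    "volume": 0.50,  "blood_flow": 390.0,  "eliminating": false},
    {"name": "liver",   "volume": 2.30,  "blood_flow": 25.35,  "eliminating": true},
    {"name": "kidney",  "volume": 0.31,  "blood_flow": 74.10,  "eliminating": true},
    {"name": "gut",     "volume": 1.65,  "blood_flow": 50.70,  "eliminating": false},
    {"name": "spleen",  "volume": 0.15,  "blood_flow": 11.70,  "eliminating": false},
    {"name": "muscle",  "volume": 28.00, "blood_flow": 66.30,  "eliminating": false},
    {"name": "adipose", "volume": 15.50, "blood_flow": 19.50,  "eliminating": false},
    {"name": "skin",    "volume": 3.30,  "blood_flow": 19.50,  "eliminating": false},
    {"name": "brain",   "volume": 1.45,  "blood_flow": 46.80,  "eliminating": false},
    {"name": "heart",   "volume": 0.33,  "blood_flow": 15.60,  "eliminating": false},
    {"name": "bone",    "volume": 9.50,  "blood_flow": 19.50,  "eliminating": false},
    {"name": "rest",    "volume": 0.93,  "blood_flow": 40.95,  "eliminating": false},
    {"name": "arterial_blood", "volume": 1.70, "blood_flow": 0.0, "eliminating": false},
    {"name": "venous_blood",   "volume": 3.90, "blood_flow": 0.0, "eliminating": false}
  ]
}
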