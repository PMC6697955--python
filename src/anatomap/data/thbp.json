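[
  {"id": "head", "formal_name": "head", "aliases": ["cephalic region"], "parent": null},
  {"id": "eye", "formal_name": "eye", "aliases": ["ocular region"], "parent": "head"},
  {"id": "ear", "formal_name": "ear", "aliases": [], "parent": "head"},
  {"id": "nose", "formal_name": "nose", "aliases": ["nasal cavity"], "parent": "head"},
  {"id": "mouth", "formal_name": "mouth", "aliases": ["oral cavity"], "parent": "head"},
  {"id": "brain", "formal_name": "brain", "aliases": ["cerebrum"], "parent": "head"},
  {"id": "skull", "formal_name": "skull", "aliases": ["cranium"], "parent": "head"},
  {"id": "face", "formal_name": "face", "aliases": [], "parent": "head"},
  {"id": "scalp", "formal_name": "scalp", "aliases": [], "parent": "head"},

  {"id": "neck", "formal_name": "neck", "aliases": ["cervical region", "carotid artery"], "parent": null},
  {"id": "throat", "formal_name": "throat", "aliases": [], "parent": "neck"},
  {"id": "trachea", "formal_name": "trachea", "aliases": ["windpipe"], "parent": "neck"},
  {"id": "larynx", "formal_name": "larynx", "aliases": ["voice box"], "parent": "neck"},
  {"id": "pharynx", "formal_name": "pharynx", "aliases": [], "parent": "neck"},
  {"id": "thyroid", "formal_name": "thyroid", "aliases": ["thyroid gland"], "parent": "neck"},

  {"id": "chest", "formal_name": "chest", "aliases": ["thorax", "thoracic cavity"], "parent": null},
  {"id": "heart", "formal_name": "heart", "aliases": ["cardiac", "myocardium", "mitral valve", "aortic valve", "tricuspid valve"], "parent": "chest"},
  {"id": "lung", "formal_name": "lung", "aliases": ["pulmonary"], "parent": "chest"},
  {"id": "esophagus", "formal_name": "esophagus", "aliases": ["gullet"], "parent": "chest"},
  {"id": "breast", "formal_name": "breast", "aliases": [], "parent": "chest"},
  {"id": "rib", "formal_name": "rib", "aliases": ["costal"], "parent": "chest"},
  {"id": "diaphragm", "formal_name": "diaphragm", "aliases": [], "parent": "chest"},

  {"id": "abdomen", "formal_name": "abdomen", "aliases": ["abd", "abdn", "peritoneal cavity", "abdominal cavity", "enterocoelia"], "parent": null},
  {"id": "stomach", "formal_name": "stomach", "aliases": ["gastric"], "parent": "abdomen"},
  {"id": "liver", "formal_name": "liver", "aliases": ["hepatic"], "parent": "abdomen"},
  {"id": "colon", "formal_name": "colon", "aliases": ["large intestine", "large bowel", "sigmoid colon"], "parent": "abdomen"},
  {"id": "intestine", "formal_name": "intestine", "aliases": ["bowel", "small intestine"], "parent": "abdomen"},
  {"id": "kidney", "formal_name": "kidney", "aliases": ["renal"], "parent": "abdomen"},
  {"id": "spleen", "formal_name": "spleen", "aliases": ["splenic"], "parent": "abdomen"},
  {"id": "pancreas", "formal_name": "pancreas", "aliases": ["pancreatic"], "parent": "abdomen"},
  {"id": "gallbladder", "formal_name": "gallbladder", "aliases": ["gall bladder"], "parent": "abdomen"},
  {"id": "appendix", "formal_name": "appendix", "aliases": [], "parent": "abdomen"},

  {"id": "pelvis", "formal_name": "pelvis", "aliases": ["pelvic cavity"], "parent": null},
  {"id": "bladder", "formal_name": "bladder", "aliases": ["urinary bladder"], "parent": "pelvis"},
  {"id": "uterus", "formal_name": "uterus", "aliases": ["womb"], "parent": "pelvis"},
  {"id": "ovary", "formal_name": "ovary", "aliases": ["ovarian"], "parent": "pelvis"},
  {"id": "prostate", "formal_name": "prostate", "aliases": [], "parent": "pelvis"},
  {"id": "rectum", "formal_name": "rectum", "aliases": ["rectal"], "parent": "pelvis"},
  {"id": "groin", "formal_name": "groin", "aliases": ["inguinal region"], "parent": "pelvis"},

  {"id": "back", "formal_name": "back", "aliases": ["dorsum"], "parent": null},
  {"id": "spine", "formal_name": "spine", "aliases": ["vertebral column", "spinal column", "vertebra", "backbone"], "parent": "back"},

  {"id": "hip", "formal_name": "hip", "aliases": ["coxa"], "parent": null},

  {"id": "extremity", "formal_name": "extremity", "aliases": ["limb"], "parent": null},
  {"id": "upper-extremity", "formal_name": "upper extremity", "aliases": ["upper limb", "arm"], "parent": "extremity"},
  {"id": "hand", "formal_name": "hand", "aliases": ["palm"], "parent": "upper-extremity"},
  {"id": "wrist", "formal_name": "wrist", "aliases": [], "parent": "upper-extremity"},
  {"id": "elbow", "formal_name": "elbow", "aliases": [], "parent": "upper-extremity"},
  {"id": "shoulder", "formal_name": "shoulder", "aliases": [], "parent": "upper-extremity"},
  {"id": "lower-extremity", "formal_name": "lower extremity", "aliases": ["lower limb", "leg"], "parent": "extremity"},
  {"id": "foot", "formal_name": "foot", "aliases": [], "parent": "lower-extremity"},
  {"id": "ankle", "formal_name": "ankle", "aliases": [], "parent": "lower-extremity"},
  {"id": "knee", "formal_name": "knee", "aliases": [], "parent": "lower-extremity"},
  {"id": "thigh", "formal_name": "thigh", "aliases": ["femoral region"], "parent": "lower-extremity"},

  {"id": "trunk", "formal_name": "trunk", "aliases": ["torso"], "parent": null},
  {"id": "nerve", "formal_name": "nerve", "aliases": [], "parent": "trunk"},
  {"id": "blood", "formal_name": "blood", "aliases": [], "parent": "trunk"},
  {"id": "bone", "formal_name": "bone", "aliases": [], "parent": "trunk"},
  {"id": "muscle", "formal_name": "muscle", "aliases": ["muscular"], "parent": "trunk"},
  {"id": "skin", "formal_name": "skin", "aliases": [], "parent": "trunk"},
  {"id": "vein", "formal_name": "vein", "aliases": ["venous"], "parent": "trunk"},
  {"id": "artery", "formal_name": "artery", "aliases": [], "parent": "trunk"}
]
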