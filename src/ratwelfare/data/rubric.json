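[
  {
    "name": "BodyCondition",
    "levels": {
      "0": "Normal",
      "1": "Altered body condition/weight loss of <10%",
      "2": "Emaciated/weight loss of 10-20%",
      "3": "Weight loss of >20%"
    },
    "euthanasia_levels": [
      3
    ]
  },
  {
    "name": "Posture",
    "levels": {
      "0": "Normal",
      "1": "Curved"
    },
    "euthanasia_levels": []
  },
  {
    "name": "Hair",
    "levels": {
      "0": "Normal",
      "1": "Lack of grooming",
      "2": "Very bad-looking hair, dirty tail, severe chromodacryorrhea"
    },
    "euthanasia_levels": []
  },
  {
    "name": "GrimaceEyes",
    "levels": {
      "0": "Normal",
      "1": "Narrowing of the orbital area",
      "2": "Moderate anemia/cataracts, eyes fully closed",
      "3": "Severe anemia/corneal ulcers"
    },
    "euthanasia_levels": [
      3
    ]
  },
  {
    "name": "GrimaceEars",
    "levels": {
      "0": "Normal",
      "1": "Dropped ears, forward whiskers (stiffened)",
      "2": "Floppy and curved ears, whiskers turned forward and crumpled (clusters)"
    },
    "euthanasia_levels": []
  },
  {
    "name": "GrimaceNose",
    "levels": {
      "0": "Normal",
      "1": "Flattening and elongating the tip of the nose",
      "2": "Flattening of the cheeks (cheek appearance)"
    },
    "euthanasia_levels": []
  },
  {
    "name": "Walk",
    "levels": {
      "0": "Normal",
      "3": "Walking on the tip of the extremities"
    },
    "euthanasia_levels": [
      3
    ]
  },
  {
    "name": "Skin",
    "levels": {
      "0": "Absence",
      "1": "Skin injuries/infections <5 mm",
      "2": "Skin injuries/infections >5 mm",
      "3": "Presence of necrosis"
    },
    "euthanasia_levels": [
      3
    ]
  },
  {
    "name": "MentalStatus",
    "levels": {
      "0": "Normal",
      "1": "Inactive",
      "2": "Moribund",
      "3": "Stupor/coma"
    },
    "euthanasia_levels": [
      3
    ]
  },
  {
    "name": "ResponseToStimuli",
    "levels": {
      "0": "Normal",
      "1": "Moderate",
      "2": "Moderate with vocalization",
      "3": "Violent"
    },
    "euthanasia_levels": []
  },
  {
    "name": "Hydration",
    "levels": {
      "0": "Normal",
      "1": "Abnormal skin pinch test (>2 s)"
    },
    "euthanasia_levels": []
  },
  {
    "name": "Stool",
    "levels": {
      "0": "Solid",
      "1": "Pasty diarrhea",
      "2": "Liquid diarrhea"
    },
    "euthanasia_levels": []
  },
  {
    "name": "Convulsions",
    "levels": {
      "0": "Absence",
      "3": "Presence"
    },
    "euthanasia_levels": []
  },
  {
    "name": "Abdomen",
    "levels": {
      "0": "Normal",
      "1": "Vocalization on palpation",
      "2": "Distended"
    },
    "euthanasia_levels": []
  }
]
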