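{
 "features": [
  {
   "name": "Coronary atherosclerosis of native coronary artery",
   "domain": "PMH",
   "prev_neg": 0.01013,
   "prev_pos": 0.06383,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Presence of coronary angioplasty implant and graft",
   "domain": "PMH",
   "prev_neg": 0.02243,
   "prev_pos": 0.08511,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Atherosclerotic heart disease of native coronary artery without angina pectoris",
   "domain": "PMH",
   "prev_neg": 0.07091,
   "prev_pos": 0.17021,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Atrial fibrillation",
   "domain": "PMH",
   "prev_neg": 0.01954,
   "prev_pos": 0.04255,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Cerebral infarction, unspecified",
   "domain": "PMH",
   "prev_neg": 0.02533,
   "prev_pos": 0.10638,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Dissection of vertebral artery",
   "domain": "PMH",
   "prev_neg": 0.00072,
   "prev_pos": 0.17021,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Occlusion and stenosis of carotid artery without mention of cerebral infarction",
   "domain": "PMH",
   "prev_neg": 0.00507,
   "prev_pos": 0.06383,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Transient ischemic attack (TIA), and cerebral infarction without residual deficits",
   "domain": "PMH",
   "prev_neg": 0.01447,
   "prev_pos": 0.08511,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Personal history of transient ischemic attack (TIA), and cerebral infarction without residual deficits",
   "domain": "PMH",
   "prev_neg": 0.0644,
   "prev_pos": 0.10638,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Essential (primary) hypertension",
   "domain": "PMH",
   "prev_neg": 0.41751,
   "prev_pos": 0.46809,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Hyperlipidemia, unspecified",
   "domain": "PMH",
   "prev_neg": 0.18958,
   "prev_pos": 0.29787,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Type 2 diabetes mellitus without complications",
   "domain": "PMH",
   "prev_neg": 0.12229,
   "prev_pos": 0.19149,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Migraine, unspecified, not intractable, without status migrainosus",
   "domain": "PMH",
   "prev_neg": 0.0152,
   "prev_pos": 0.02128,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Migraine, unspecified, without mention of intractable migraine without mention of status migrainosus",
   "domain": "PMH",
   "prev_neg": 0.00724,
   "prev_pos": 0.04255,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Morbid obesity",
   "domain": "PMH",
   "prev_neg": 0.00434,
   "prev_pos": 0.02128,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Long term (current) use of anticoagulants",
   "domain": "PMH",
   "prev_neg": 0.05861,
   "prev_pos": 0.19149,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Long term (current) use of antithrombotics/antiplatelets",
   "domain": "PMH",
   "prev_neg": 0.01664,
   "prev_pos": 0.08511,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Long term (current) use of aspirin",
   "domain": "PMH",
   "prev_neg": 0.11433,
   "prev_pos": 0.31915,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Smoking - active",
   "domain": "PMH",
   "prev_neg": 0.12084,
   "prev_pos": 0.12766,
   "documentation_rate": 1.0,
   "established": true
  },
  {
   "name": "Smoking - former",
   "domain": "PMH",
   "prev_neg": 0.39001,
   "prev_pos": 0.44681,
   "documentation_rate": 1.0,
   "established": false
  },
  {
   "name": "Dizziness",
   "domain": "ROS",
   "prev_neg": 0.95,
   "prev_pos": 0.95,
   "documentation_rate": 0.95,
   "established": false
  },
  {
   "name": "Headache",
   "domain": "ROS",
   "prev_neg": 0.25,
   "prev_pos": 0.3,
   "documentation_rate": 0.8,
   "established": false
  },
  {
   "name": "Nausea",
   "domain": "ROS",
   "prev_neg": 0.35,
   "prev_pos": 0.35,
   "documentation_rate": 0.8,
   "established": false
  },
  {
   "name": "Vision changes",
   "domain": "ROS",
   "prev_neg": 0.05,
   "prev_pos": 0.15,
   "documentation_rate": 0.6,
   "established": false
  },
  {
   "name": "Weakness",
   "domain": "ROS",
   "prev_neg": 0.1,
   "prev_pos": 0.2,
   "documentation_rate": 0.6,
   "established": false
  },
  {
   "name": "Chest pain",
   "domain": "ROS",
   "prev_neg": 0.05,
   "prev_pos": 0.05,
   "documentation_rate": 0.5,
   "established": false
  },
  {
   "name": "Nystagmus",
   "domain": "PE",
   "prev_neg": 0.08,
   "prev_pos": 0.15,
   "documentation_rate": 0.7,
   "established": false
  },
  {
   "name": "Ataxia on exam",
   "domain": "PE",
   "prev_neg": 0.05,
   "prev_pos": 0.2,
   "documentation_rate": 0.6,
   "established": false
  },
  {
   "name": "Focal motor deficit",
   "domain": "PE",
   "prev_neg": 0.03,
   "prev_pos": 0.12,
   "documentation_rate": 0.6,
   "established": false
  },
  {
   "name": "Dysmetria",
   "domain": "PE",
   "prev_neg": 0.03,
   "prev_pos": 0.1,
   "documentation_rate": 0.5,
   "established": false
  }
 ],
 "numerics": [
  {
   "name": "age",
   "mean_neg": 63.6,
   "mean_pos": 67.7,
   "sd": 15.6,
   "documentation_rate": 1.0,
   "low": 18,
   "high": 105
  },
  {
   "name": "systolic_bp",
   "mean_neg": 134.0,
   "mean_pos": 140.0,
   "sd": 18.0,
   "documentation_rate": 0.95,
   "low": 70,
   "high": 260
  },
  {
   "name": "heart_rate",
   "mean_neg": 80.0,
   "mean_pos": 84.0,
   "sd": 14.0,
   "documentation_rate": 0.95,
   "low": 30,
   "high": 200
  },
  {
   "name": "pain_rating",
   "mean_neg": 2.0,
   "mean_pos": 2.0,
   "sd": 2.5,
   "documentation_rate": 0.5,
   "low": 0,
   "high": 10,
   "integer": true
  }
 ]
}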