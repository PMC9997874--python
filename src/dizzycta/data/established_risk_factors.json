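{
 "established_risk_factors": [
  "Coronary atherosclerosis of native coronary artery",
  "Presence of coronary angioplasty implant and graft",
  "Atherosclerotic heart disease of native coronary artery without angina pectoris",
  "Atrial fibrillation",
  "Cerebral infarction, unspecified",
  "Dissection of vertebral artery",
  "Occlusion and stenosis of carotid artery without mention of cerebral infarction",
  "Transient ischemic attack (TIA), and cerebral infarction without residual deficits",
  "Personal history of transient ischemic attack (TIA), and cerebral infarction without residual deficits",
  "Essential (primary) hypertension",
  "Hyperlipidemia, unspecified",
  "Type 2 diabetes mellitus without complications",
  "Migraine, unspecified, not intractable, without status migrainosus",
  "Migraine, unspecified, without mention of intractable migraine without mention of status migrainosus",
  "Morbid obesity",
  "Long term (current) use of anticoagulants",
  "Long term (current) use of antithrombotics/antiplatelets",
  "Long term (current) use of aspirin",
  "Smoking - active"
 ]
}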