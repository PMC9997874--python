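{
 "categories": {
  "No PMH of cerebrovascular event (dissection, stroke, or TIA, including unexplained dysarthria/aphasia, ataxia, incoordination, and visual disturbances)": [
   "Dissection of vertebral artery",
   "Transient ischemic attack (TIA), and cerebral infarction without residual deficits",
   "Other cerebral infarction",
   "Aphasia",
   "Dysarthria and anarthria",
   "Ataxic gait",
   "Ataxia, unspecified",
   "Lack of coordination",
   "Other lack of coordination",
   "Visual Disturbances"
  ],
  "No PMH of specific vascular risk factors (coronary artery disease, diabetes, current/long-term smoking, migraines)": [
   "Coronary atherosclerosis of native coronary artery",
   "Atherosclerotic heart disease of native coronary artery without angina pectoris",
   "Presence of aortocoronary bypass graft",
   "Type II or unspecified type diabetes mellitus without mention of complication, not stated as uncontrolled",
   "Encounter for long-term (current) use of insulin",
   "Long term (current) use of insulin",
   "Nicotine dependence, cigarettes, uncomplicated",
   "Smoking - active",
   "Migraine, unspecified, without mention of intractable migraine without mention of status migrainosus",
   "Migraine, unspecified, not intractable, without status migrainosus"
  ],
  "No current long-term medication use of anticoagulation or anti-platelet agents": [
   "Encounter for long-term (current) use of aspirin",
   "Long term (current) use of antithrombotics/antiplatelets",
   "Long term (current) use of anticoagulants"
  ]
 }
}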