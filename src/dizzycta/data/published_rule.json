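{
 "name": "published-dizziness-cta-rule",
 "description": "Rule-out criteria for acute vascular pathology on CTA in adult ED dizziness presentations: an encounter is excluded (no acute vascular pathology expected) iff none of the listed features is present.",
 "inclusion_criteria": "Adult ED patients with chief complaint of dizziness; excludes encounters with an alternative indication for neurovascular imaging (focal deficit, trauma, thunderclap headache).",
 "categories": [
  {
   "label": "No PMH of cerebrovascular event (dissection, stroke, or TIA, including unexplained dysarthria/aphasia, ataxia, incoordination, and visual disturbances)",
   "features": [
    {
     "name": "Dissection of vertebral artery",
     "domain": "PMH"
    },
    {
     "name": "Transient ischemic attack (TIA), and cerebral infarction without residual deficits",
     "domain": "PMH"
    },
    {
     "name": "Other cerebral infarction",
     "domain": "PMH"
    },
    {
     "name": "Aphasia",
     "domain": "PMH"
    },
    {
     "name": "Dysarthria and anarthria",
     "domain": "PMH"
    },
    {
     "name": "Ataxic gait",
     "domain": "PMH"
    },
    {
     "name": "Ataxia, unspecified",
     "domain": "PMH"
    },
    {
     "name": "Lack of coordination",
     "domain": "PMH"
    },
    {
     "name": "Other lack of coordination",
     "domain": "PMH"
    },
    {
     "name": "Visual Disturbances",
     "domain": "PMH"
    }
   ]
  },
  {
   "label": "No PMH of specific vascular risk factors (coronary artery disease, diabetes, current/long-term smoking, migraines)",
   "features": [
    {
     "name": "Coronary atherosclerosis of native coronary artery",
     "domain": "PMH"
    },
    {
     "name": "Atherosclerotic heart disease of native coronary artery without angina pectoris",
     "domain": "PMH"
    },
    {
     "name": "Presence of aortocoronary bypass graft",
     "domain": "PMH"
    },
    {
     "name": "Type II or unspecified type diabetes mellitus without mention of complication, not stated as uncontrolled",
     "domain": "PMH"
    },
    {
     "name": "Encounter for long-term (current) use of insulin",
     "domain": "PMH"
    },
    {
     "name": "Long term (current) use of insulin",
     "domain": "PMH"
    },
    {
     "name": "Nicotine dependence, cigarettes, uncomplicated",
     "domain": "PMH"
    },
    {
     "name": "Smoking - active",
     "domain": "PMH"
    },
    {
     "name": "Migraine, unspecified, without mention of intractable migraine without mention of status migrainosus",
     "domain": "PMH"
    },
    {
     "name": "Migraine, unspecified, not intractable, without status migrainosus",
     "domain": "PMH"
    }
   ]
  },
  {
   "label": "No current long-term medication use of anticoagulation or anti-platelet agents",
   "features": [
    {
     "name": "Encounter for long-term (current) use of aspirin",
     "domain": "PMH"
    },
    {
     "name": "Long term (current) use of antithrombotics/antiplatelets",
     "domain": "PMH"
    },
    {
     "name": "Long term (current) use of anticoagulants",
     "domain": "PMH"
    }
   ]
  }
 ]
}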