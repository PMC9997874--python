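{
 "description": "Hand-executed trace of the covering loop on the 40-case fixture: three perfect features partition the 6 positives with coverage 3/2/1 and appear in no negative, so forest importance orders them by coverage and each iteration's largest all-negative leaf path admits them in that order.",
 "selected_order": ["F1", "F2", "F3"],
 "covered_new": [3, 2, 1],
 "uncovered_positives": [3, 1, 0]
}
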