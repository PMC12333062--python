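drug_name,adcc_status,antibody_type,target
Blinatumomab,negative,mouse,anti-CD19/CD3
Brentuximab vedotin,negative,chimeric,anti-CD30
Cetuximab,positive,chimeric,anti-EGFR
Isatuximab,positive,chimeric,anti-CD38
Rituximab,positive,chimeric,anti-CD20
Alemtuzumab,positive,humanized,anti-CD52
Atezolizumab,negative,humanized,anti-PD-L1
Bevacizumab,negative,humanized,anti-VEGF
Elotuzumab,positive,humanized,anti-SLAMF7
Gemtuzumab ozogamicin,negative,humanized,anti-CD33
Inotuzumab ozogamicin,negative,humanized,anti-CD22
Mogamulizumab,positive,humanized,anti-CCR4
Obinutuzumab,positive,humanized,anti-CD20
Pembrolizumab,negative,humanized,anti-PD-1
Pertuzumab,positive,humanized,anti-HER2
Polatuzumab vedotin,positive,humanized,anti-CD79b
Trastuzumab,positive,humanized,anti-HER2
Trastuzumab emtansine,positive,humanized,anti-HER2
Avelumab,positive,fully_human,anti-PD-L1
Daratumumab,positive,fully_human,anti-CD38
Durvalumab,negative,fully_human,anti-PD-L1
Ipilimumab,positive,fully_human,anti-CTLA-4
Nivolumab,negative,fully_human,anti-PD-1
Panitumumab,negative,fully_human,anti-EGFR
Ramucirumab,negative,fully_human,anti-VEGFR2
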