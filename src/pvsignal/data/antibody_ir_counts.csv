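drug_name,ir_cases,report_total,ror_reported,ci_low_reported,ci_high_reported,signal_reported
Blinatumomab,59,244,17.91,13.31,24.10,True
Brentuximab vedotin,5,1295,0.21,0.09,0.50,False
Cetuximab,591,4799,10.99,9.90,12.19,True
Isatuximab,9,169,3.07,1.57,6.02,True
Rituximab,64,5958,0.57,0.45,0.74,False
Alemtuzumab,4,57,4.11,1.49,11.37,True
Atezolizumab,33,3894,0.45,0.32,0.64,False
Bevacizumab,53,19237,0.12,0.09,0.16,False
Elotuzumab,12,807,0.82,0.46,1.45,False
Gemtuzumab ozogamicin,7,1794,0.21,0.10,0.44,False
Inotuzumab ozogamicin,3,99,1.70,0.54,5.37,False
Mogamulizumab,44,1011,2.51,1.85,3.41,True
Obinutuzumab,39,421,5.65,4.05,7.89,True
Pembrolizumab,46,11716,0.19,0.14,0.26,False
Pertuzumab,96,1179,5.04,4.07,6.24,True
Polatuzumab vedotin,1,329,0.17,0.02,1.18,False
Trastuzumab,155,3568,2.61,2.21,3.09,True
Trastuzumab emtansine,5,616,0.44,0.18,1.07,False
Avelumab,25,278,5.44,3.59,8.22,True
Daratumumab,42,916,2.65,1.94,3.63,True
Durvalumab,9,2851,0.17,0.09,0.32,False
Ipilimumab,55,9351,0.30,0.23,0.39,False
Nivolumab,142,18246,0.38,0.32,0.45,False
Panitumumab,36,2724,0.72,0.52,1.01,False
Ramucirumab,57,3563,0.88,0.67,1.15,False
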