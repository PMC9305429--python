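compound_id,name,retention_time,family
8,coumaric acid hexoside,3.23,hydroxycinnamic_acid
14,ferulic acid hexoside,4.10,hydroxycinnamic_acid
15,hydroxycinnamic acid glucoside,4.31,phenylpropane
16,cinnamic acid derivative,4.40,phenylpropane
21,coumaric acid derivative,4.90,hydroxycinnamic_acid
37,luteoline-7-O-glucuronide,5.60,flavone
51,depside 51,6.45,depside
53,rosmarinic acid,6.52,hydroxycinnamic_acid
55,depside 55,6.66,depside
56,depside 56,6.71,depside
57,depside 57,7.08,depside
59,depside 59,7.16,depside
66,depside 66,7.56,depside
73,depside 73,8.27,depside
74,depside 74,8.46,depside
77,depside 77,9.07,depside
93,linalyl acetate,12.79,monoterpene_ester
94,diterpene 94,12.85,diterpene
95,diterpene 95,12.85,diterpene
96,diterpene 96,13.28,diterpene
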