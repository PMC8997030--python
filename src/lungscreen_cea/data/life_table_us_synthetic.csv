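# SYNTHETIC life table: an approximation of a recent US total-population
# period life table (unisex qx, ages 55-85), constructed for this package
# because no published table is bundled. Values are plausible but are NOT
# copied from any official publication; swap in an official age,qx CSV via
# --life-table for exact reproduction against a specific table edition.
age,qx
55,0.00723
56,0.00776
57,0.00829
58,0.00881
59,0.00936
60,0.00996
61,0.01060
62,0.01127
63,0.01198
64,0.01274
65,0.01358
66,0.01453
67,0.01560
68,0.01679
69,0.01811
70,0.01962
71,0.02129
72,0.02306
73,0.02495
74,0.02707
75,0.02953
76,0.03240
77,0.03564
78,0.03925
79,0.04326
80,0.04779
81,0.05288
82,0.05860
83,0.06503
84,0.07223
85,0.08028
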