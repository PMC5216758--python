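gene,rsid,comparison,frequency,ethnicity,section,k,n_cases,n_controls,model,or,ci_low,ci_high,p,ph,i2,allelic_or,allelic_ci_low,allelic_ci_high,allelic_p,allelic_ph,allelic_i2,grade,label
IL-1β,rs1143627,T vs C,0.47,All ancestries,all,8,2211,1854,ADD,0.83,0.72,0.96,0.01,0.062,47.9,,,,,,,ABA,Moderate
miR-196,rs11614913,T vs C,0.47,All ancestries,all,12,5703,6580,ADD,1.13,1.04,1.23,0.004,0.005,59.2,,,,,,,ACC,Weak
IL28B,rs12979860,C vs T,0.27,All ancestries,all,9,2803,1653,ADD,1.22,1.00,1.49,0.043,0.006,62.8,,,,,,,BCC,Weak
XPD,rs1799793,G vs A,0.16,Asian,all,5,2005,2164,ADD,1.26,1.03,1.55,0.024,0.066,54.6,,,,,,,BCC,Weak
TGF-β1,rs1800469,C vs T,0.46,All ancestries,all,11,3180,4424,ADD,1.18,1.01,1.37,0.034,0,76.1,,,,,,,ACC,Weak
HFE,rs1800562,G vs A,0.05,All ancestries,all,11,1225,3858,ADD,1.44,1.02,2.03,0.039,0.03,51.2,,,,,,,ACC,Weak
NQO1,rs1800566,C vs T,0.41,All ancestries,all,3,745,1091,ADD,1.34,1.17,1.54,0,0.404,0,,,,,,,AAA,Strong
TNF-α,rs1800629,G vs A,0.10,All ancestries,all,20,3414,3979,ADD,1.45,1.09,1.94,0.012,0.000,80.0,,,,,,,BCC,Weak
TNF-α,rs1800630,C vs A,0.18,All ancestries,all,7,1679,1833,ADD,1.39,1.10,1.74,0.005,0.023,59.2,,,,,,,BCB,Weak
IL6,rs1800795,G vs C,0.21,All ancestries,all,3,219,522,ADD,0.72,0.53,0.98,0.039,0.993,0,,,,,,,BAA,Moderate
IL10,rs1800872,A vs C,0.44,Asian,all,6,1540,2173,ADD,1.13,1.02,1.26,0.023,0.387,4.6,,,,,,,BAC,Weak
IL8,rs2227306,C vs T,0.36,Asian,all,3,486,698,ADD,0.79,0.62,1.00,0.045,0.176,42.4,,,,,,,BBA,Moderate
MDM2,rs2279744,T vs G,0.47,All ancestries,all,11,2905,3495,ADD,0.73,0.61,0.88,0.001,0.000,78.4,,,,,,,ACA,Weak
CTLA4,rs231775,G vs A,0.34,Asian,all,3,1369,1426,ADD,1.34,1.03,1.75,0.029,0.011,77.7,,,,,,,BCB,Weak
XRCC1,rs25487,A vs G,0.41,All ancestries,all,23,4851,5508,ADD,1.24,1.10,1.39,0,0.000,66.0,,,,,,,ACB,Weak
HLA-DQ,rs2856718,A vs G,0.44,Asian,all,3,2756,3681,ADD,0.73,0.67,0.78,0,0.395,0,,,,,,,BAA,Moderate
miR-146a,rs2910164,C vs G,0.42,All ancestries,all,16,6179,8246,ADD,1.10,1.03,1.18,0.004,0.067,37.2,,,,,,,ABC,Weak
TNF-α,rs361525,G vs A,0.05,All ancestries,all,12,1529,1836,ADD,1.44,1.04,2.00,0.027,0.102,36.1,,,,,,,ABA,Moderate
EGF,rs4444903,G vs A,0.40,All ancestries,all,12,2304,3664,ADD,0.83,0.74,0.94,0.003,0.037,46.8,,,,,,,ABA,Moderate
PNPLA3,rs738409,C vs G,0.33,Caucasian,all,9,1234,2624,ADD,2.01,1.56,2.35,0,0.000,74.3,,,,,,,BCB,Weak
BIRC5,rs9904341,G vs C,0.46,All ancestries,all,3,473,933,ADD,0.84,0.71,0.99,0.032,0.886,0,,,,,,,BAA,Moderate
IL8,rs4073,A vs T,0.49,Asian,ethnic,3,691,906,ADD,1.22,1.06,1.42,0.007,0.583,0.0,,,,,,,BAA,Moderate
Cox-2,rs20417,G vs C,0.07,Asian,ethnic,4,1168,1438,ADD,1.94,1.03,3.67,0.041,0.393,0.0,,,,,,,BAA,Moderate
EPHX1,rs1051740,C vs T,0.30,Caucasian,ethnic,3,249,495,ADD,1.46,1.14,1.86,0.002,0.393,0.0,,,,,,,BAA,Moderate
HFE,rs1799945,C vs G,0.17,African,ethnic,3,235,362,ADD,1.73,1.27,2.37,0.001,0.567,0.0,,,,,,,BAA,Moderate
MTHFR,rs1801133,C vs T,0.41,Asian,ethnic,7,2427,3449,ADD,1.09,1.01,1.18,0.038,0.713,0.0,,,,,,,AAC,Weak
OGG1,rs1052133,C vs G,0.407455,Asian,dom_rec,9,2424,2271,REC,1.34,1.02,1.77,0.039,0.000,72.5,1.21,0.92,1.59,0.182,0.000,88.8,ACC,weak
MTHFR,rs1801131,A vs C,0.400447,ALL,dom_rec,6,2030,3096,DOM,0.66,0.45,0.98,0.038,0.219,27.4,0.96,0.87,1.06,0.42,0.783,0.0,ABA,Moderate
XRCC3,rs861539,C vs T,0.145481,Asian,dom_rec,7,2331,2759,DOM,2.89,1.57,5.31,0.001,0.014,62.5,1.21,0.92,1.59,0.182,0.000,88.8,ACC,weak
GSTP1,rs1695,A vs G,0.47543,Asian,dom_rec,4,902,1051,DOM,1.65,1.18,2.32,0.004,0.559,0.0,1.08,0.82,1.42,0.6,0.054,60.7,BAA,Moderate
IL-1β,rs16944,C vs T,0.478646,Asian,dom_rec,6,998,1037,REC,0.74,0.56,0.99,0.044,0.221,28.6,0.88,0.68,1.15,0.359,0.009,67.3,ABA,Moderate
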