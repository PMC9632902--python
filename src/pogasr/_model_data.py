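"""Published empirical amino-acid replacement model parameters.

Each model is stored as the 190 lower-triangle exchangeability
coefficients (column-major over the PAML amino-acid order) plus the
20 equilibrium frequencies, as published for JTT, LG, WAG and
Dayhoff.
"""

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

JTT_RATES = [
    58.0, 54.0, 81.0, 56.0, 57.0, 105.0,
    179.0, 27.0, 36.0, 30.0, 35.0, 54.0,
    15.0, 194.0, 378.0, 475.0, 9.0, 11.0,
    298.0, 45.0, 16.0, 113.0, 310.0, 29.0,
    137.0, 328.0, 22.0, 38.0, 646.0, 44.0,
    5.0, 74.0, 101.0, 64.0, 126.0, 20.0,
    17.0, 528.0, 34.0, 86.0, 58.0, 81.0,
    391.0, 47.0, 12.0, 263.0, 30.0, 10.0,
    15.0, 503.0, 232.0, 8.0, 70.0, 16.0,
    10.0, 49.0, 767.0, 130.0, 112.0, 11.0,
    7.0, 26.0, 15.0, 4.0, 15.0, 59.0,
    38.0, 4.0, 46.0, 31.0, 9.0, 5.0,
    59.0, 69.0, 17.0, 23.0, 7.0, 31.0,
    78.0, 14.0, 223.0, 42.0, 115.0, 209.0,
    62.0, 323.0, 26.0, 597.0, 9.0, 72.0,
    292.0, 43.0, 4.0, 164.0, 53.0, 51.0,
    18.0, 24.0, 20.0, 119.0, 26.0, 12.0,
    9.0, 181.0, 18.0, 5.0, 18.0, 30.0,
    32.0, 10.0, 7.0, 45.0, 23.0, 6.0,
    6.0, 27.0, 14.0, 5.0, 24.0, 201.0,
    33.0, 55.0, 8.0, 47.0, 16.0, 56.0,
    45.0, 33.0, 40.0, 115.0, 73.0, 46.0,
    8.0, 573.0, 11.0, 229.0, 21.0, 479.0,
    89.0, 10.0, 40.0, 245.0, 9.0, 32.0,
    961.0, 14.0, 388.0, 248.0, 102.0, 59.0,
    25.0, 52.0, 24.0, 180.0, 65.0, 4.0,
    21.0, 47.0, 103.0, 10.0, 8.0, 14.0,
    43.0, 16.0, 29.0, 226.0, 24.0, 18.0,
    323.0, 17.0, 92.0, 12.0, 53.0, 536.0,
    62.0, 285.0, 118.0, 6.0, 10.0, 23.0,
    477.0, 35.0, 63.0, 38.0, 12.0, 21.0,
    112.0, 71.0, 25.0, 16.0,
]

JTT_FREQS = [
    0.07674792325207676, 0.051690948309051694, 0.04264495735504265, 0.05154394845605155,
    0.019802980197019805, 0.04075195924804075, 0.06182993817006184, 0.07315192684807316,
    0.022943977056022944, 0.05376094623905377, 0.0919039080960919, 0.05867594132405868,
    0.02382597617402383, 0.040125959874040135, 0.05090094909905091, 0.06876493123506877,
    0.05856494143505857, 0.014260985739014262, 0.0321019678980321, 0.066004933995066,
]

LG_RATES = [
    0.425093, 0.276818, 0.395144, 2.489084, 0.969894, 1.038545,
    2.06604, 0.358858, 0.14983, 0.395337, 0.536518, 1.124035,
    0.253701, 1.177651, 4.727182, 2.139501, 0.180717, 0.218959,
    2.54787, 0.751878, 0.123954, 0.534551, 2.807908, 0.36397,
    0.390192, 2.426601, 0.126991, 0.301848, 6.326067, 0.484133,
    0.052722, 0.332533, 0.858151, 0.578987, 0.593607, 0.31444,
    0.170887, 5.076149, 0.528768, 1.695752, 0.541712, 1.437645,
    4.509238, 0.191503, 0.068427, 2.145078, 0.371004, 0.089525,
    0.161787, 4.008358, 2.000679, 0.045376, 0.612025, 0.083688,
    0.062556, 0.523386, 5.24387, 0.844926, 0.927114, 0.01069,
    0.015076, 0.282959, 0.025548, 0.017416, 0.394456, 1.240275,
    0.42586, 0.02989, 0.135107, 0.037967, 0.084808, 0.003499,
    0.569265, 0.640543, 0.320627, 0.594007, 0.013266, 0.89368,
    1.105251, 0.075382, 2.784478, 1.14348, 0.670128, 1.165532,
    1.959291, 4.128591, 0.267959, 4.813505, 0.072854, 0.582457,
    3.234294, 1.672569, 0.035855, 0.624294, 1.223828, 1.080136,
    0.236199, 0.257336, 0.210332, 0.348847, 0.423881, 0.044265,
    0.069673, 1.807177, 0.173735, 0.018811, 0.419409, 0.611973,
    0.604545, 0.077852, 0.120037, 0.245034, 0.311484, 0.008705,
    0.044261, 0.296636, 0.139538, 0.089586, 0.196961, 1.73999,
    0.129836, 0.268491, 0.054679, 0.076701, 0.108882, 0.366317,
    0.697264, 0.442472, 0.682139, 0.508851, 0.990012, 0.584262,
    0.597054, 5.306834, 0.119013, 4.145067, 0.159069, 4.273607,
    1.112727, 0.078281, 0.064105, 1.033739, 0.11166, 0.232523,
    10.649107, 0.1375, 6.312358, 2.592692, 0.24906, 0.182287,
    0.302936, 0.619632, 0.299648, 1.702745, 0.656604, 0.023918,
    0.390322, 0.748683, 1.136863, 0.049906, 0.131932, 0.185202,
    1.798853, 0.099849, 0.34696, 2.020366, 0.696175, 0.481306,
    1.898718, 0.094464, 0.361819, 0.165001, 2.457121, 7.803902,
    0.654683, 1.338132, 0.571468, 0.095131, 0.089613, 0.296501,
    6.472279, 0.248862, 0.400547, 0.098369, 0.140825, 0.245841,
    2.188158, 3.151815, 0.18951, 0.249313,
]

LG_FREQS = [
    0.07906592093407908, 0.05594094405905594, 0.04197695802304198, 0.053051946948053055,
    0.012936987063012939, 0.040766959233040766, 0.07158592841407159, 0.05733694266305734,
    0.022354977645022357, 0.06215693784306216, 0.09908090091909909, 0.0645999354000646,
    0.022950977049022953, 0.042301957698042306, 0.04403995596004404, 0.0611969388030612,
    0.05328694671305329, 0.012065987934012068, 0.034154965845034156, 0.06914693085306915,
]

WAG_RATES = [
    0.551571, 0.509848, 0.738998, 1.02704, 0.908598, 1.58285,
    1.41672, 0.316954, 0.193335, 0.397915, 0.906265, 0.893496,
    0.210494, 1.43855, 3.37079, 2.12111, 0.113133, 0.240735,
    2.00601, 0.635346, 0.147304, 0.528191, 3.0355, 0.439157,
    0.584665, 2.13715, 0.186979, 0.497671, 5.35142, 0.683162,
    0.102711, 0.679489, 1.22419, 0.554413, 1.16392, 0.381533,
    0.251849, 5.42942, 0.265256, 1.54364, 0.947198, 1.12556,
    3.95629, 0.554236, 0.131528, 3.01201, 0.198221, 0.0961621,
    0.195081, 3.97423, 2.03006, 0.0719167, 1.086, 0.196246,
    0.0302949, 0.616783, 6.17416, 0.865584, 0.930676, 0.039437,
    0.0848047, 0.479855, 0.103754, 0.0467304, 0.423984, 1.07176,
    0.374866, 0.129767, 0.325711, 0.152335, 0.0988179, 0.021352,
    0.306674, 0.248972, 0.170135, 0.384287, 0.0740339, 0.390482,
    0.39802, 0.109404, 1.40766, 0.512984, 0.71707, 0.543833,
    1.00214, 5.46947, 0.330052, 4.29411, 0.113917, 0.869489,
    3.8949, 1.54526, 0.0999208, 0.933372, 1.02887, 0.857928,
    0.215737, 0.22771, 0.301281, 0.567717, 0.570025, 0.127395,
    0.154263, 2.58443, 0.315124, 0.0811339, 0.682355, 0.704939,
    0.822765, 0.156557, 0.196303, 0.588731, 0.24941, 0.0304501,
    0.0613037, 0.373558, 0.1741, 0.049931, 0.24357, 1.34182,
    0.225833, 0.336983, 0.103604, 0.187247, 0.13819, 0.499462,
    0.890432, 0.404141, 0.679371, 0.696198, 0.740169, 0.473307,
    0.262569, 3.87344, 0.118358, 3.17097, 0.323832, 4.25746,
    1.05947, 0.0999288, 0.31944, 1.45816, 0.212483, 0.42017,
    7.8213, 0.257555, 4.85402, 2.11517, 0.415844, 0.344739,
    0.326622, 0.665309, 0.398618, 1.80034, 0.934276, 0.088836,
    0.556896, 0.96713, 1.38698, 0.137505, 0.133264, 0.305434,
    1.19063, 0.171329, 0.493905, 1.51612, 0.515706, 0.428437,
    2.05845, 0.161444, 0.545931, 0.171903, 1.52964, 6.45428,
    0.649892, 1.61328, 0.795384, 0.139405, 0.216046, 0.314887,
    4.37802, 0.523742, 0.786993, 0.232739, 0.110864, 0.291148,
    1.38823, 2.48539, 0.365369, 0.31473,
]

WAG_FREQS = [
    0.08662790866279087, 0.04397200439720044, 0.0390894039089404, 0.057045105704510574,
    0.019307801930780195, 0.03672810367281037, 0.05805890580589058, 0.08325180832518084,
    0.024431302443130246, 0.04846600484660049, 0.08620900862090086, 0.062028606202860624,
    0.019502701950270197, 0.03843190384319038, 0.045763104576310464, 0.06951790695179069,
    0.06101270610127062, 0.014385901438590145, 0.035274203527420354, 0.07089560708956072,
]

DAYHOFF_RATES = [
    27.0, 98.0, 120.0, 36.0, 89.0, 198.0,
    240.0, 23.0, 65.0, 41.0, 26.0, 72.0,
    18.0, 250.0, 409.0, 371.0, 0.0, 24.0,
    208.0, 32.0, 0.0, 23.0, 246.0, 1.0,
    9.0, 240.0, 64.0, 15.0, 464.0, 90.0,
    14.0, 103.0, 154.0, 26.0, 201.0, 8.0,
    24.0, 905.0, 0.0, 103.0, 148.0, 139.0,
    535.0, 77.0, 34.0, 318.0, 1.0, 14.0,
    42.0, 495.0, 229.0, 23.0, 95.0, 15.0,
    0.0, 134.0, 1153.0, 125.0, 86.0, 24.0,
    0.0, 71.0, 0.0, 0.0, 13.0, 95.0,
    66.0, 0.0, 0.0, 18.0, 0.0, 0.0,
    11.0, 28.0, 44.0, 0.0, 0.0, 0.0,
    0.0, 19.0, 161.0, 16.0, 0.0, 96.0,
    49.0, 716.0, 28.0, 606.0, 18.0, 73.0,
    153.0, 114.0, 0.0, 153.0, 56.0, 53.0,
    0.0, 0.0, 35.0, 81.0, 43.0, 61.0,
    11.0, 83.0, 30.0, 0.0, 51.0, 79.0,
    34.0, 0.0, 22.0, 37.0, 10.0, 0.0,
    7.0, 27.0, 17.0, 15.0, 34.0, 234.0,
    30.0, 0.0, 0.0, 54.0, 7.0, 44.0,
    26.0, 0.0, 48.0, 94.0, 35.0, 22.0,
    27.0, 127.0, 44.0, 257.0, 46.0, 336.0,
    196.0, 12.0, 24.0, 192.0, 0.0, 37.0,
    889.0, 18.0, 527.0, 157.0, 32.0, 17.0,
    33.0, 46.0, 28.0, 175.0, 243.0, 0.0,
    33.0, 96.0, 136.0, 0.0, 13.0, 10.0,
    92.0, 17.0, 62.0, 104.0, 0.0, 0.0,
    258.0, 11.0, 46.0, 13.0, 76.0, 698.0,
    12.0, 245.0, 78.0, 0.0, 0.0, 48.0,
    550.0, 75.0, 34.0, 30.0, 0.0, 42.0,
    157.0, 61.0, 0.0, 28.0,
]

DAYHOFF_FREQS = [
    0.08712691287308713, 0.04090395909604091, 0.04043195956804044, 0.04687195312804687,
    0.033473966526033475, 0.03825496174503826, 0.04952995047004953, 0.08861191138808862,
    0.033617966382033626, 0.03688596311403689, 0.08535691464308537, 0.08048191951808048,
    0.014752985247014754, 0.03977196022803978, 0.05067994932005069, 0.06957693042306959,
    0.05854194145805854, 0.010493989506010494, 0.02991597008402992, 0.06471793528206472,
]

EMPIRICAL_MODELS = {
    "JTT": (JTT_RATES, JTT_FREQS),
    "LG": (LG_RATES, LG_FREQS),
    "WAG": (WAG_RATES, WAG_FREQS),
    "Dayhoff": (DAYHOFF_RATES, DAYHOFF_FREQS),
}
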