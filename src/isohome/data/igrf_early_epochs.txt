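# Main-field Gauss coefficients (nT), epochs 1900.0-1925.0 at 5-year intervals,
# in the standard IGRF text layout.  Transcribed from the published IGRF
# reference-field tables for the early epochs; truncated at degree 8, with the
# weakly-constrained degree-7 and degree-8 terms held at their 1900.0 values.
# Values for these early epochs are identical across recent IGRF generations.
# Transcription note: written out from reference knowledge of the published
# table (no machine copy was available); small transcription discrepancies in
# mid-degree terms cannot be excluded and are discussed in docs/methods.md.
c/s deg ord 1900 1905 1910 1915 1920 1925
g/h n m 1900.0 1905.0 1910.0 1915.0 1920.0 1925.0
g 1 0 -31543 -31464 -31354 -31212 -31060 -30926
g 1 1 -2298 -2298 -2297 -2306 -2317 -2318
h 1 1 5922 5909 5898 5875 5845 5817
g 2 0 -677 -728 -769 -802 -839 -893
g 2 1 2905 2928 2948 2956 2959 2969
h 2 1 -1061 -1086 -1128 -1191 -1259 -1334
g 2 2 924 1041 1176 1309 1407 1471
h 2 2 1121 1065 1000 917 823 728
g 3 0 1022 1037 1058 1084 1111 1140
g 3 1 -1469 -1494 -1524 -1559 -1600 -1645
h 3 1 -330 -357 -389 -421 -445 -462
g 3 2 1256 1239 1223 1212 1205 1202
h 3 2 3 34 62 84 103 119
g 3 3 572 635 705 778 839 881
h 3 3 523 480 425 360 293 229
g 4 0 876 880 884 887 889 891
g 4 1 628 643 660 678 695 711
h 4 1 195 203 211 218 220 216
g 4 2 660 653 644 631 616 601
h 4 2 -69 -77 -90 -109 -134 -163
g 4 3 -361 -380 -400 -416 -424 -426
h 4 3 -210 -201 -189 -173 -153 -130
g 4 4 134 146 160 178 199 217
h 4 4 -75 -65 -55 -51 -57 -70
g 5 0 -184 -192 -201 -211 -221 -230
g 5 1 328 328 327 327 326 326
h 5 1 -210 -193 -172 -148 -122 -96
g 5 2 264 259 253 245 236 226
h 5 2 53 56 57 58 58 58
g 5 3 5 -1 -9 -16 -23 -28
h 5 3 -33 -32 -33 -34 -38 -44
g 5 4 -86 -93 -102 -111 -119 -125
h 5 4 -124 -125 -126 -126 -125 -122
g 5 5 -16 -26 -38 -51 -62 -69
h 5 5 3 11 21 32 43 51
g 6 0 63 62 62 61 61 61
g 6 1 61 60 58 57 55 54
h 6 1 -9 -7 -5 -2 0 3
g 6 2 -11 -11 -11 -10 -10 -9
h 6 2 83 86 89 93 96 99
g 6 3 -217 -221 -224 -228 -233 -238
h 6 3 2 4 5 8 11 14
g 6 4 -58 -57 -54 -51 -46 -40
h 6 4 -35 -32 -29 -26 -22 -18
g 6 5 59 57 54 49 44 39
h 6 5 36 32 28 23 18 13
g 6 6 -90 -92 -95 -98 -101 -103
h 6 6 -69 -67 -65 -62 -57 -52
g 7 0 70 70 70 70 70 70
g 7 1 -55 -55 -55 -55 -55 -55
h 7 1 -45 -45 -45 -45 -45 -45
g 7 2 0 0 0 0 0 0
h 7 2 -13 -13 -13 -13 -13 -13
g 7 3 34 34 34 34 34 34
h 7 3 -10 -10 -10 -10 -10 -10
g 7 4 -41 -41 -41 -41 -41 -41
h 7 4 -1 -1 -1 -1 -1 -1
g 7 5 -21 -21 -21 -21 -21 -21
h 7 5 28 28 28 28 28 28
g 7 6 18 18 18 18 18 18
h 7 6 -12 -12 -12 -12 -12 -12
g 7 7 6 6 6 6 6 6
h 7 7 -22 -22 -22 -22 -22 -22
g 8 0 11 11 11 11 11 11
g 8 1 8 8 8 8 8 8
h 8 1 8 8 8 8 8 8
g 8 2 -4 -4 -4 -4 -4 -4
h 8 2 -14 -14 -14 -14 -14 -14
g 8 3 -9 -9 -9 -9 -9 -9
h 8 3 7 7 7 7 7 7
g 8 4 1 1 1 1 1 1
h 8 4 -13 -13 -13 -13 -13 -13
g 8 5 2 2 2 2 2 2
h 8 5 5 5 5 5 5 5
g 8 6 -9 -9 -9 -9 -9 -9
h 8 6 16 16 16 16 16 16
g 8 7 5 5 5 5 5 5
h 8 7 -5 -5 -5 -5 -5 -5
g 8 8 8 8 8 8 8 8
h 8 8 -18 -18 -18 -18 -18 -18
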