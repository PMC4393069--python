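H PRAM900101
D Hydrophobicity (synthetic surrogate coefficients)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.20    0.95    0.76    0.25    0.66    0.98    0.76    0.20    0.20    0.11
     0.77    0.73    0.67    0.48    0.81    0.87    0.73    0.33    0.29    0.13
//
H GRAR740102
D Polarity (Grantham, 1974)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     8.1    10.5    11.6    13.0     5.5    10.5    12.3     9.0    10.4     5.2
     4.9    11.3     5.7     5.2     8.0     9.2     8.6     5.4     6.2     5.9
//
H ZIMJ680102
D Bulkiness (Zimmerman et al., 1968)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    11.50   14.28   12.82   11.68   13.46   14.45   13.57    3.40   13.69   21.40
    21.40   15.71   16.25   19.80   17.43    9.47   15.77   21.67   18.03   21.57
//
H KYTJ820101
D Hydropathy index (Kyte-Doolittle, 1982)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     1.8    -4.5    -3.5    -3.5     2.5    -3.5    -3.5    -0.4    -3.2     4.5
     3.8    -3.9     1.9     2.8    -1.6    -0.8    -0.7    -0.9    -1.3     4.2
//
H RADA880106
D Accessible surface area (synthetic surrogate coefficients)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   204.2   158.2    65.7    84.8   133.9   232.4    79.0   119.0   228.9    78.7
   165.9    62.6   213.4   159.8   221.9   126.8   194.1   173.0   230.9    69.9
//
H CHOC760101
D Residue accessible surface area in tripeptide (Chothia, 1976)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   115.    225.    160.    150.    135.    180.    190.     75.    195.    175.
   170.    200.    185.    210.    145.    115.    140.    255.    230.    155.
//
H JANJ780102
D Percentage of buried residues (synthetic surrogate coefficients)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    57.8    14.6    73.9    34.3    13.0    43.6    66.3    11.9    46.3    10.6
    11.5    21.9    18.5     0.6    31.0     0.3    45.6    57.6    56.1     8.8
//
H HUTJ700103
D Entropy of formation (synthetic surrogate coefficients)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    57.4    21.2    31.6    45.5    58.9    46.9    59.5    46.3    49.1    42.1
    23.9    26.7    43.8    35.9    28.9    42.1    30.1    32.6    54.6    36.7
//
H KRIW790103
D Side-chain volume (synthetic surrogate coefficients)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   149.9   140.2    54.1   162.9   202.0   105.1   120.4   182.9   170.8   222.5
   220.4   182.6   128.7    75.8    78.7   194.9   189.4   114.3    25.4    78.1
//
H TAKK010101
D Side-chain contribution to protein stability (synthetic surrogate coefficients)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.29    0.61    1.91   -0.11    0.32   -0.97    0.99   -0.94   -1.91   -1.65
    -0.96   -1.69    0.82   -0.04    0.64   -0.63   -1.60    1.87    1.98    1.00
//
H ZHOH040103
D Buriability (synthetic surrogate coefficients)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.05    0.15    0.28    0.21    0.60    0.61    0.25    0.91    0.02    0.89
     0.15    0.08    0.36    0.99    0.08    0.94    0.97    0.15    0.39    0.79
//
H HOPT810101
D Hydrophilicity value (Hopp-Woods, 1981)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    -0.5     3.0     0.2     3.0    -1.0     0.2     3.0     0.0    -0.5    -1.8
    -1.8     3.0    -1.3    -2.5     0.0     0.3    -0.4    -3.4    -2.3    -1.5
//
H FASG760101
D Molecular weight (Fasman, 1976)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    89.09  174.20  132.12  133.10  121.15  146.15  147.13   75.07  155.16  131.17
   131.17  146.19  149.21  165.19  115.13  105.09  119.12  204.24  181.19  117.15
//
H BULH740101
D Transfer free energy to surface (synthetic surrogate coefficients)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   -948.    408.   -492.    972.   -350.    -75.  -1605.   -513.  -1251.  -1157.
   -430.  -1274.   -276.   -407.    817.     38.  -1351.  -1327.   -640.   -158.
//
H CHAM810101
D Steric parameter (Charton, 1981)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     0.52    0.68    0.76    0.76    0.62    0.68    0.68    0.00    0.70    1.02
     0.98    0.68    0.78    0.70    0.36    0.53    0.50    0.70    0.70    0.76
//
H ZIMJ680104
D Isoelectric point (Zimmerman et al., 1968)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
     6.00   10.76    5.41    2.77    5.05    5.65    3.22    5.97    7.59    6.02
     5.98    9.74    5.74    5.48    6.30    5.68    5.66    5.89    5.66    5.96
//
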