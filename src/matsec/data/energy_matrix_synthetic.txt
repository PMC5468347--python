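# Synthetic 20x20 interaction-energy predictor matrix (arbitrary units).
# Stand-in constructed from a hydrophobicity outer product, an
# electrostatic term and seeded symmetric noise; replace with any
# symmetric 20x20 matrix file of the same format.
A C D E F G H I K L M N P Q R S T V W Y
-0.6827 -0.7662 1.0597 1.1049 -0.8149 0.3246 0.4829 -1.4182 0.7761 -0.9272 -0.7845 0.8661 0.0841 0.3343 0.8565 -0.1890 0.1846 -0.9348 -0.0891 -0.0830
-0.7662 -0.5186 1.0058 1.1309 -0.5734 -0.5920 0.3403 -1.8655 1.2702 -1.8085 -0.8846 1.3127 0.5170 0.5209 0.9542 0.2510 0.2360 -1.7143 0.0387 -0.0307
1.0597 1.0058 -0.1345 -0.7085 1.0105 0.0965 -1.2622 2.0027 -2.0281 0.9934 1.1074 -0.7962 -0.3254 -0.9028 -1.9791 0.0508 0.3327 1.3355 -0.4171 -0.4445
1.1049 1.1309 -0.7085 -0.2953 0.5111 0.1275 -0.9880 1.3389 -1.6871 1.2345 0.6245 -0.8662 -0.3069 -1.1048 -2.0842 -0.6580 0.1932 1.8058 -0.0767 -0.2149
-0.8149 -0.5734 1.0105 0.5111 -1.8142 -0.8992 0.3565 -1.9283 1.3237 -1.6455 -0.7052 1.1741 1.0919 1.0712 1.6500 -0.3314 -0.1572 -1.9662 0.3408 0.5699
0.3246 -0.5920 0.0965 0.1275 -0.8992 0.1303 0.1213 -0.3240 0.3115 -0.0763 0.2709 -0.1032 -0.2856 -0.0555 0.1980 -0.1124 -0.3999 0.2077 -0.1906 -0.5598
0.4829 0.3403 -1.2622 -0.9880 0.3565 0.1213 -0.3471 1.2114 -0.8036 1.3495 0.7982 -1.4515 -0.2272 -1.0931 -0.9287 -0.2016 0.2300 1.5738 0.2060 -0.1371
-1.4182 -1.8655 2.0027 1.3389 -1.9283 -0.3240 1.2114 -3.0421 1.6073 -1.8293 -1.3975 1.4251 0.6021 1.6165 2.4507 0.1811 -0.0221 -2.5933 -0.0262 0.7743
0.7761 1.2702 -2.0281 -1.6871 1.3237 0.3115 -0.8036 1.6073 -0.9649 1.5036 0.7498 -1.5134 -0.3932 -0.8583 -1.2399 -0.1770 -0.3304 2.0424 -0.0141 -0.2624
-0.9272 -1.8085 0.9934 1.2345 -1.6455 -0.0763 1.3495 -1.8293 1.5036 -1.7605 -1.1431 1.4516 0.2132 1.5812 1.5762 0.0963 0.2952 -1.8400 0.3170 0.7098
-0.7845 -0.8846 1.1074 0.6245 -0.7052 0.2709 0.7982 -1.3975 0.7498 -1.1431 -0.7080 0.6419 0.1193 0.7404 0.8384 0.0000 -0.3737 -1.5267 0.1403 -0.2163
0.8661 1.3127 -0.7962 -0.8662 1.1741 -0.1032 -1.4515 1.4251 -1.5134 1.4516 0.6419 -1.4179 -0.4586 -1.1047 -1.0117 -0.1944 0.1237 1.7682 0.0572 -0.6057
0.0841 0.5170 -0.3254 -0.3069 1.0919 -0.2856 -0.2272 0.6021 -0.3932 0.2132 0.1193 -0.4586 -0.0501 -0.8841 -0.0757 -0.0413 -0.2120 0.5921 0.0853 -0.4190
0.3343 0.5209 -0.9028 -1.1048 1.0712 -0.0555 -1.0931 1.6165 -0.8583 1.5812 0.7404 -1.1047 -0.8841 -1.0803 -1.4828 -0.1553 0.0082 1.9733 0.0331 -0.3603
0.8565 0.9542 -1.9791 -2.0842 1.6500 0.1980 -0.9287 2.4507 -1.2399 1.5762 0.8384 -1.0117 -0.0757 -1.4828 -1.0067 -0.5392 0.0887 1.7654 -0.1666 -0.6429
-0.1890 0.2510 0.0508 -0.6580 -0.3314 -0.1124 -0.2016 0.1811 -0.1770 0.0963 0.0000 -0.1944 -0.0413 -0.1553 -0.5392 0.0506 -0.3179 -0.3504 0.2231 0.1063
0.1846 0.2360 0.3327 0.1932 -0.1572 -0.3999 0.2300 -0.0221 -0.3304 0.2952 -0.3737 0.1237 -0.2120 0.0082 0.0887 -0.3179 -0.4954 0.2898 -0.1326 -0.2784
-0.9348 -1.7143 1.3355 1.8058 -1.9662 0.2077 1.5738 -2.5933 2.0424 -1.8400 -1.5267 1.7682 0.5921 1.9733 1.7654 -0.3504 0.2898 -2.5079 -0.1921 0.6365
-0.0891 0.0387 -0.4171 -0.0767 0.3408 -0.1906 0.2060 -0.0262 -0.0141 0.3170 0.1403 0.0572 0.0853 0.0331 -0.1666 0.2231 -0.1326 -0.1921 0.2156 -0.0507
-0.0830 -0.0307 -0.4445 -0.2149 0.5699 -0.5598 -0.1371 0.7743 -0.2624 0.7098 -0.2163 -0.6057 -0.4190 -0.3603 -0.6429 0.1063 -0.2784 0.6365 -0.0507 -0.7994
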