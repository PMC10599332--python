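# Os 76 190.23
2.0000 51.7376 59.9555
2.0249 20.3887 38.2536
2.0290 -11.2347 35.8213
2.0330 -2.5015 124.0730
2.0371 33.6023 112.9675
2.0469 63.1626 91.0868
2.0513 69.1445 83.0333
2.0919 61.5819 46.6334
2.0948 61.6464 45.2634
2.1439 45.8717 33.7985
2.1941 48.7329 32.7191
2.2455 50.8485 31.6595
2.2981 52.4247 30.6208
2.3520 53.5020 29.6020
2.4071 53.8607 28.6059
2.4496 52.0538 27.8672
2.4545 50.6237 27.7836
2.4595 50.4974 32.3918
2.4635 52.0988 32.3095
2.4644 52.3189 32.2910
2.4816 54.5068 31.9423
2.5212 56.6610 31.1677
2.5307 57.0198 30.9876
2.5802 58.3563 30.0814
2.6407 59.6438 29.1171
2.7025 60.5368 28.1737
2.7659 60.8546 27.2522
2.7836 60.4670 27.0029
2.7892 59.9360 26.9247
2.7948 59.9329 28.6784
2.8004 60.6869 28.5881
2.8199 61.6550 28.2801
2.8307 61.9767 28.1139
2.8758 62.9001 27.4510
2.8970 63.2202 27.1558
2.9648 63.9493 26.2835
3.0343 64.1661 25.4464
3.0399 64.0508 25.3804
3.0460 63.6800 25.3088
3.0520 63.8647 26.3552
3.0581 64.2891 26.2833
3.0795 64.9281 26.0334
3.1054 65.3989 25.7361
3.1405 65.8933 25.3418
3.1781 66.3373 24.9300
3.2526 67.0826 24.1456
3.3288 67.7075 23.3835
3.4068 68.2543 22.6422
3.4866 68.7385 21.9215
3.5683 69.1706 21.2205
3.6519 69.5670 20.5386
3.7374 69.9131 19.8748
3.8250 70.2238 19.2291
3.9146 70.5019 18.6024
4.0063 70.7785 17.9905
4.1002 71.0230 17.3946
4.1962 71.2169 16.8155
4.2945 71.3883 16.2538
4.3951 71.5390 15.7094
4.4981 71.6705 15.1815
4.6035 71.7842 14.6699
4.7113 71.8815 14.1746
4.8217 71.9636 13.6943
4.9347 72.0451 13.2287
5.0503 72.0990 12.7765
5.1686 72.1481 12.3385
5.2897 72.1771 11.9143
5.4136 72.1950 11.5037
5.5404 72.2093 11.1062
5.6702 72.2154 10.7205
5.8031 72.2026 10.3469
5.9390 72.1808 9.9858
6.0782 72.1503 9.6363
6.2206 72.1144 9.2981
6.3663 72.0672 8.9711
6.5154 72.0119 8.6550
6.6681 71.9486 8.3492
6.8243 71.8774 8.0538
6.9842 71.7982 7.7681
7.1478 71.7106 7.4921
7.3152 71.6145 7.2255
7.4866 71.5094 6.9677
7.6620 71.3945 6.7186
7.8415 71.2692 6.4779
8.0252 71.1323 6.2454
8.2132 70.9824 6.0209
8.4057 70.8177 5.8038
8.6026 70.6359 5.5943
8.8041 70.4339 5.3919
9.0104 70.2116 5.1954
9.2215 69.9550 5.0050
9.4375 69.6559 4.8215
9.6586 69.3018 4.6445
9.8849 68.8696 4.4738
10.1165 68.3164 4.3093
10.3535 67.5513 4.1506
10.5960 66.2807 3.9976
10.8384 62.0246 3.8530
10.8443 61.6224 3.8496
10.8601 59.8082 3.8404
10.8819 59.8564 10.1923
10.9036 62.0831 10.1580
10.9797 64.5463 10.0394
11.0983 66.0361 9.8586
11.1971 66.7380 9.7116
11.3583 67.4639 9.4787
11.6244 68.0982 9.1104
11.8968 68.2802 8.7548
12.1755 67.8787 8.4121
12.3478 66.3252 8.2099
12.3726 65.2321 8.1814
12.3974 65.2578 11.3634
12.4222 66.4089 11.3248
12.4607 67.1693 11.2653
12.5088 67.7041 11.1916
12.7526 68.7845 10.8292
12.7566 68.7911 10.8234
12.9291 68.5113 10.5781
12.9550 68.0157 10.5420
12.9810 68.0916 12.1546
13.0069 68.7329 12.1176
13.0514 69.2535 12.0546
13.0977 69.6036 11.9896
13.3570 70.7456 11.6352
13.3572 70.7462 11.6350
13.6701 71.5958 11.2266
13.9903 72.2216 10.8265
14.3181 72.7226 10.4395
14.6535 73.1385 10.0655
14.9968 73.4903 9.7038
15.3482 73.7918 9.3542
15.7077 74.0523 9.0163
16.0757 74.2786 8.6897
16.4524 74.4790 8.3734
16.8378 74.6511 8.0679
17.2323 74.8021 7.7727
17.6360 74.9336 7.4877
18.0491 75.0485 7.2125
18.4720 75.1486 6.9467
18.9047 75.2355 6.6901
19.3476 75.3106 6.4424
19.8009 75.3751 6.2033
20.2648 75.4301 5.9725
20.7396 75.4764 5.7498
21.2254 75.5150 5.5349
21.7227 75.5469 5.3275
22.2316 75.5732 5.1273
22.7524 75.5925 4.9341
23.2855 75.6065 4.7479
23.8310 75.6158 4.5682
24.3893 75.6207 4.3950
24.9607 75.6223 4.2280
25.5454 75.6195 4.0670
26.1439 75.6136 3.9118
26.7564 75.6048 3.7621
27.3832 75.5947 3.6168
28.0248 75.5810 3.4769
28.6813 75.5647 3.3422
29.3532 75.5461 3.2127
30.0409 75.5254 3.0880
30.7447 75.5031 2.9680
31.4650 75.4792 2.8525
32.2021 75.4538 2.7415
32.9566 75.4272 2.6346
33.7286 75.3994 2.5317
34.5188 75.3705 2.4328
35.3275 75.3406 2.3376
36.1552 75.3098 2.2460
37.0022 75.2782 2.1579
37.8691 75.2457 2.0732
38.7562 75.2124 1.9917
39.6642 75.1784 1.9133
40.5934 75.1436 1.8379
41.5445 75.1081 1.7653
42.5177 75.0717 1.6956
43.5138 75.0346 1.6285
44.5333 74.9965 1.5640
45.5766 74.9575 1.5020
46.6443 74.9175 1.4423
47.7371 74.8787 1.3849
48.8554 74.8360 1.3296
50.0000 74.7918 1.2764
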