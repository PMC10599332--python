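# Nd 60 144.242
2.0000 53.1344 19.3011
2.0469 53.4451 18.7120
2.0948 53.7308 18.1381
2.1439 53.9877 17.5778
2.1941 54.2206 17.0324
2.2455 54.4492 16.5003
2.2981 54.6379 15.9821
2.3520 54.8077 15.4769
2.4071 54.9596 14.9858
2.4635 55.0950 14.5077
2.5212 55.2147 14.0427
2.5802 55.3197 13.5908
2.6407 55.4156 13.1498
2.7025 55.4929 12.7219
2.7659 55.5580 12.3051
2.8307 55.6128 11.9005
2.8970 55.6545 11.5076
2.9648 55.6855 11.1264
3.0343 55.7083 10.7536
3.1054 55.7214 10.3902
3.1781 55.7272 10.0382
3.2526 55.7197 9.6966
3.3288 55.7029 9.3659
3.4068 55.6773 9.0456
3.4866 55.6432 8.7355
3.5683 55.6009 8.4352
3.6519 55.5504 8.1445
3.7374 55.4918 7.8634
3.8250 55.4251 7.5909
3.9146 55.3572 7.3274
4.0063 55.2831 7.0719
4.1002 55.1895 6.8241
4.1962 55.0866 6.5847
4.2945 54.9750 6.3531
4.3951 54.8513 6.1292
4.4981 54.7156 5.9126
4.6035 54.5679 5.7032
4.7113 54.4039 5.5010
4.8217 54.2225 5.3054
4.9347 54.0207 5.1163
5.0503 53.7944 4.9336
5.1686 53.5380 4.7571
5.2897 53.2437 4.5866
5.4136 52.9000 4.4218
5.5404 52.4889 4.2626
5.6702 51.9876 4.1086
5.8031 51.3245 3.9596
5.9390 50.3800 3.8157
6.0782 48.7256 3.6768
6.1894 44.3704 3.5712
6.2018 41.8811 3.5597
6.2142 41.9632 10.6373
6.2206 43.5590 10.6137
6.2266 44.4405 10.5916
6.2701 47.1623 10.4347
6.3663 49.1452 10.1048
6.3942 49.4465 10.0133
6.5154 49.9993 9.6369
6.6681 49.4363 9.2693
6.7018 48.4808 9.1910
6.7153 47.2411 9.1599
6.7287 47.4745 12.6852
6.7422 48.7387 12.6372
6.7892 50.2710 12.4728
6.8243 50.8558 12.3525
6.9237 51.8206 12.0237
6.9842 52.1368 11.8315
7.1046 51.8030 11.4795
7.1189 51.2655 11.4409
7.1331 51.3458 13.1740
7.1474 52.0472 13.1341
7.1478 52.0599 13.1330
7.1973 52.9851 12.9964
7.3152 54.0667 12.6794
7.3398 54.2348 12.6147
7.4866 55.0659 12.2381
7.6620 55.8046 11.8051
7.8415 56.3992 11.3857
8.0252 56.8947 10.9795
8.2132 57.3170 10.5860
8.4057 57.6792 10.2048
8.6026 57.9933 9.8362
8.8041 58.2674 9.4796
9.0104 58.5086 9.1332
9.2215 58.7197 8.7974
9.4375 58.9049 8.4732
9.6586 59.0679 8.1602
9.8849 59.2099 7.8580
10.1165 59.3342 7.5663
10.3535 59.4429 7.2848
10.5960 59.5375 7.0133
10.8443 59.6196 6.7511
11.0983 59.6905 6.4983
11.3583 59.7511 6.2544
11.6244 59.8026 6.0191
11.8968 59.8458 5.7921
12.1755 59.8815 5.5733
12.4607 59.9161 5.3622
12.7526 59.9384 5.1580
13.0514 59.9550 4.9612
13.3572 59.9665 4.7715
13.6701 59.9777 4.5884
13.9903 59.9799 4.4119
14.3181 59.9813 4.2417
14.6535 59.9760 4.0776
14.9968 59.9675 3.9196
15.3482 59.9560 3.7675
15.7077 59.9420 3.6211
16.0757 59.9256 3.4801
16.4524 59.9070 3.3444
16.8378 59.8864 3.2138
17.2323 59.8639 3.0881
17.6360 59.8399 2.9671
18.0491 59.8145 2.8508
18.4720 59.7879 2.7388
18.9047 59.7601 2.6310
19.3476 59.7310 2.5273
19.8009 59.7009 2.4275
20.2648 59.6698 2.3316
20.7396 59.6378 2.2393
21.2254 59.6050 2.1505
21.7227 59.5715 2.0651
22.2316 59.5372 1.9830
22.7524 59.5021 1.9040
23.2855 59.4664 1.8280
23.8310 59.4299 1.7550
24.3893 59.3926 1.6848
24.9607 59.3546 1.6172
25.5454 59.3158 1.5523
26.1439 59.2761 1.4899
26.7564 59.2354 1.4299
27.3832 59.1966 1.3720
28.0248 59.1532 1.3163
28.6813 59.1085 1.2628
29.3532 59.0653 1.2114
30.0409 59.0171 1.1620
30.7447 58.9668 1.1145
31.4650 58.9183 1.0687
32.2021 58.8624 1.0247
32.9566 58.8030 0.9825
33.7286 58.7394 0.9421
34.5188 58.6706 0.9033
35.3275 58.5952 0.8660
36.1552 58.5114 0.8303
37.0022 58.4168 0.7961
37.8691 58.3074 0.7632
38.7562 58.1772 0.7317
39.6642 58.0163 0.7015
40.5934 57.8054 0.6725
41.5445 57.5015 0.6446
42.5177 56.9687 0.6180
43.4383 55.1730 0.5943
43.5138 54.4068 0.5924
43.5254 54.1959 0.5921
43.6126 54.2103 3.4172
43.6997 55.2107 3.4068
44.0047 56.3272 3.3706
44.5333 57.0825 3.3090
44.8761 57.3765 3.2699
45.5766 57.7952 3.1919
46.6443 58.2193 3.0746
47.7371 58.5132 2.9608
48.8554 58.7376 2.8509
50.0000 58.9169 2.7447
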