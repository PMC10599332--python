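# I 53 126.90447
2.0000 48.1651 11.5676
2.0469 48.2074 11.1987
2.0948 48.2401 10.8405
2.1439 48.2641 10.4916
2.1941 48.2815 10.1522
2.2455 48.2877 9.8222
2.2981 48.2856 9.5015
2.3520 48.2758 9.1894
2.4071 48.2578 8.8867
2.4635 48.2322 8.5925
2.5212 48.2052 8.3067
2.5802 48.1683 8.0292
2.6407 48.1180 7.7594
2.7025 48.0602 7.4983
2.7659 47.9947 7.2445
2.8307 47.9214 6.9988
2.8970 47.8400 6.7607
2.9648 47.7501 6.5300
3.0343 47.6517 6.3048
3.1054 47.5438 6.0855
3.1781 47.4245 5.8736
3.2526 47.2928 5.6684
3.3288 47.1478 5.4701
3.4068 46.9878 5.2783
3.4866 46.8107 5.0928
3.5683 46.6270 4.9127
3.6519 46.4056 4.7385
3.7374 46.1657 4.5702
3.8250 45.8797 4.4069
3.9146 45.5487 4.2492
4.0063 45.1578 4.0969
4.1002 44.6835 3.9497
4.1962 44.0865 3.8077
4.2945 43.2864 3.6705
4.3951 42.0847 3.5380
4.4981 39.6223 3.4100
4.5433 36.1304 3.3561
4.5524 33.5439 3.3454
4.5616 33.4442 10.9092
4.5707 36.1304 10.8593
4.6026 39.0283 10.6881
4.6035 39.0741 10.6833
4.6937 41.3337 10.2313
4.7113 41.5089 10.1481
4.8217 40.9014 9.6973
4.8374 40.1869 9.6455
4.8471 38.9899 9.6137
4.8569 39.0315 13.3458
4.8666 40.4500 13.2956
4.9005 42.1645 13.1230
4.9347 43.0233 12.9532
4.9976 43.9930 12.6518
5.0503 44.4997 12.4096
5.1686 44.4391 11.9282
5.1724 44.3451 11.9137
5.1828 43.8009 11.8743
5.1932 43.8620 13.6605
5.2036 44.5901 13.6192
5.2399 45.5602 13.4766
5.2897 46.2859 13.2846
5.3436 46.8583 13.0815
5.4136 47.4503 12.8246
5.5404 48.2872 12.3783
5.6702 48.9546 11.9453
5.8031 49.5096 11.5255
5.9390 49.9870 11.1188
6.0782 50.3929 10.7233
6.2206 50.7453 10.3405
6.3663 51.0574 9.9697
6.5154 51.3277 9.6104
6.6681 51.5658 9.2626
6.8243 51.7773 8.9263
6.9842 51.9626 8.6008
7.1478 52.1261 8.2862
7.3152 52.2703 7.9823
7.4866 52.3974 7.6884
7.6620 52.5090 7.4045
7.8415 52.6069 7.1302
8.0252 52.6922 6.8652
8.2132 52.7662 6.6093
8.4057 52.8301 6.3621
8.6026 52.8847 6.1235
8.8041 52.9308 5.8932
9.0104 52.9689 5.6704
9.2215 53.0045 5.4549
9.4375 53.0284 5.2468
9.6586 53.0465 5.0464
9.8849 53.0636 4.8527
10.1165 53.0714 4.6661
10.3535 53.0748 4.4864
10.5960 53.0775 4.3129
10.8443 53.0732 4.1458
11.0983 53.0656 3.9850
11.3583 53.0551 3.8302
11.6244 53.0418 3.6811
11.8968 53.0271 3.5375
12.1755 53.0091 3.3994
12.4607 52.9890 3.2665
12.7526 52.9672 3.1385
13.0514 52.9437 3.0154
13.3572 52.9186 2.8969
13.6701 52.8922 2.7829
13.9903 52.8646 2.6732
14.3181 52.8359 2.5677
14.6535 52.8061 2.4662
14.9968 52.7753 2.3686
15.3482 52.7437 2.2747
15.7077 52.7112 2.1844
16.0757 52.6779 2.0975
16.4524 52.6451 2.0139
16.8378 52.6103 1.9336
17.2323 52.5748 1.8563
17.6360 52.5395 1.7820
18.0491 52.5025 1.7105
18.4720 52.4648 1.6418
18.9047 52.4264 1.5758
19.3476 52.3872 1.5124
19.8009 52.3481 1.4514
20.2648 52.3070 1.3927
20.7396 52.2647 1.3363
21.2254 52.2222 1.2821
21.7227 52.1773 1.2300
22.2316 52.1309 1.1800
22.7524 52.0834 1.1320
23.2855 52.0330 1.0858
23.8310 51.9802 1.0415
24.3893 51.9246 0.9989
24.9607 51.8654 0.9581
25.5454 51.8020 0.9189
26.1439 51.7335 0.8812
26.7564 51.6585 0.8450
27.3832 51.5759 0.8098
28.0248 51.4824 0.7760
28.6813 51.3745 0.7436
29.3532 51.2466 0.7125
30.0409 51.0895 0.6828
30.7447 50.8862 0.6543
31.4650 50.6002 0.6269
32.2021 50.1273 0.6007
32.9566 48.7935 0.5756
33.0695 48.1029 0.5720
33.1358 47.0944 0.5699
33.2022 47.0831 3.5138
33.2685 48.1351 3.5025
33.5007 49.3033 3.4630
33.7286 49.8206 3.4250
34.1641 50.3988 3.3541
34.5188 50.7083 3.2981
35.3275 51.1847 3.1762
36.1552 51.5124 3.0588
37.0022 51.7595 2.9454
37.8691 51.9555 2.8358
38.7562 52.1158 2.7299
39.6642 52.2498 2.6277
40.5934 52.3634 2.5289
41.5445 52.4606 2.4336
42.5177 52.5445 2.3416
43.5138 52.6182 2.2526
44.5333 52.6814 2.1666
45.5766 52.7365 2.0837
46.6443 52.7847 2.0037
47.7371 52.8267 1.9265
48.8554 52.8634 1.8521
50.0000 52.8953 1.7804
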