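# U 92 238.02891
2.0000 70.3705 20.1787
2.0469 70.4747 19.6596
2.0948 70.5636 19.1517
2.1439 70.6228 18.6523
2.1941 70.6591 18.1634
2.2455 70.6720 17.6841
2.2981 70.6607 17.2146
2.3520 70.6240 16.7541
2.4071 70.5605 16.3036
2.4635 70.4684 15.8623
2.5212 70.3456 15.4303
2.5802 70.1919 15.0075
2.6407 69.9974 14.5927
2.7025 69.7613 14.1876
2.7659 69.4767 13.7902
2.8307 69.1367 13.4020
2.8970 68.7310 13.0223
2.9648 68.2469 12.6513
3.0343 67.6752 12.2841
3.1054 66.9658 11.9226
3.1781 66.1221 11.5687
3.2526 64.9755 11.2232
3.3288 63.4411 10.8874
3.4068 61.2126 10.5607
3.4866 57.3038 10.2432
3.5413 49.6985 10.0346
3.5484 45.4636 10.0080
3.5556 45.8511 21.1038
3.5627 49.2723 21.2063
3.5683 50.5602 21.2866
3.5875 52.7667 21.5573
3.6519 54.6398 22.4021
3.6586 54.6305 22.4834
3.7168 51.3465 23.1275
3.7243 48.3080 23.2016
3.7317 51.9686 31.7790
3.7374 54.4923 31.7519
3.7392 54.9985 31.7432
3.7653 58.8634 31.6153
3.8250 62.7682 31.3003
3.8398 63.4469 31.2171
3.9146 67.1318 30.7422
4.0063 69.4042 29.6126
4.1002 70.9016 28.5177
4.1962 71.6384 27.4584
4.2901 70.0093 26.4769
4.2945 69.4994 26.4322
4.2987 68.6528 26.3896
4.3073 68.4978 30.7435
4.3159 70.2528 30.6529
4.3460 72.3456 30.3390
4.3951 73.9672 29.8369
4.4321 74.8178 29.4667
4.4981 76.0028 28.8227
4.6035 77.4521 27.8264
4.7113 78.5443 26.8606
4.8217 79.4175 25.9233
4.9347 80.0840 25.0149
5.0503 80.5086 24.1345
5.1665 80.1128 23.2958
5.1686 80.0556 23.2810
5.1768 79.6624 23.2236
5.1872 79.6737 24.6212
5.1975 80.2433 24.5486
5.2338 80.9662 24.2957
5.2897 81.5214 23.9142
5.3375 81.8490 23.5955
5.4136 82.2213 23.1019
5.5314 82.2215 22.3741
5.5404 82.0289 22.3200
5.5425 81.9411 22.3074
5.5535 81.9937 23.1949
5.5646 82.3811 23.1288
5.6035 82.9290 22.8994
5.6702 83.4498 22.5137
5.7144 83.7169 22.2638
5.8031 84.1676 21.7753
5.9390 84.7355 21.0558
6.0782 85.2075 20.3568
6.2206 85.6147 19.6793
6.3663 85.9713 19.0223
6.5154 86.2829 18.3853
6.6681 86.5573 17.7674
6.8243 86.8040 17.1680
6.9842 87.0158 16.5865
7.1478 87.2052 16.0231
7.3152 87.3672 15.4772
7.4866 87.5108 14.9482
7.6620 87.6299 14.4357
7.8415 87.7309 13.9398
8.0252 87.8154 13.4597
8.2132 87.8845 12.9952
8.4057 87.9396 12.5455
8.6026 87.9816 12.1105
8.8041 88.0112 11.6897
9.0104 88.0310 11.2801
9.2215 88.0388 10.8823
9.4375 88.0347 10.4983
9.6586 88.0201 10.1274
9.8849 87.9958 9.7692
10.1165 87.9623 9.4233
10.3535 87.9200 9.0894
10.5960 87.8792 8.7659
10.8443 87.8195 8.4533
11.0983 87.7552 8.1518
11.3583 87.6787 7.8603
11.6244 87.5935 7.5790
11.8968 87.4995 7.3074
12.1755 87.3961 7.0454
12.4607 87.2828 6.7926
12.7526 87.1586 6.5487
13.0514 87.0222 6.3132
13.3572 86.8721 6.0860
13.6701 86.7061 5.8669
13.9903 86.5231 5.6555
14.3181 86.3149 5.4513
14.6535 86.0779 5.2545
14.9968 85.8039 5.0645
15.3482 85.4761 4.8811
15.7077 85.0734 4.7043
16.0757 84.5456 4.5336
16.4524 83.7851 4.3688
16.8378 82.3920 4.2100
17.1145 79.0304 4.1015
17.1488 77.0273 4.0884
17.1832 76.9767 9.9277
17.2175 79.0634 9.8960
17.2323 79.5437 9.8823
17.3377 81.3572 9.7858
17.6360 83.2712 9.5192
17.6810 83.4422 9.4798
18.0491 84.4432 9.1641
18.4720 85.0756 8.8076
18.9047 85.4484 8.4640
19.3476 85.6286 8.1330
19.8009 85.6260 7.8143
20.2648 85.3672 7.5073
20.7396 84.3954 7.2117
20.8852 83.2862 7.1246
20.9271 82.2410 7.0999
20.9689 82.2828 10.0507
21.0108 83.3199 10.0186
21.1575 84.4531 9.9071
21.2254 84.7042 9.8561
21.5764 85.1685 9.5982
21.6917 84.9140 9.5155
21.7227 84.6708 9.4935
21.7352 84.4842 9.4846
21.7788 84.5392 10.9195
21.8223 85.1264 10.8874
21.9746 85.9116 10.7762
22.2316 86.6067 10.5883
22.4097 86.9419 10.4610
22.7524 87.4536 10.2226
23.2855 88.0532 9.8640
23.8310 88.5120 9.5167
24.3893 88.8860 9.1811
24.9607 89.1983 8.8567
25.5454 89.4636 8.5433
26.1439 89.6915 8.2405
26.7564 89.8889 7.9478
27.3832 90.0689 7.6630
28.0248 90.2194 7.3867
28.6813 90.3523 7.1197
29.3532 90.4660 6.8618
30.0409 90.5648 6.6128
30.7447 90.6505 6.3724
31.4650 90.7245 6.1404
32.2021 90.7882 5.9165
32.9566 90.8426 5.7004
33.7286 90.8887 5.4919
34.5188 90.9311 5.2905
35.3275 90.9627 5.0959
36.1552 90.9882 4.9081
37.0022 91.0083 4.7270
37.8691 91.0233 4.5523
38.7562 91.0338 4.3838
39.6642 91.0403 4.2212
40.5934 91.0430 4.0645
41.5445 91.0423 3.9133
42.5177 91.0436 3.7671
43.5138 91.0354 3.6259
44.5333 91.0308 3.4894
45.5766 91.0187 3.3579
46.6443 91.0046 3.2312
47.7371 90.9884 3.1092
48.8554 90.9705 2.9916
50.0000 90.9510 2.8783
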