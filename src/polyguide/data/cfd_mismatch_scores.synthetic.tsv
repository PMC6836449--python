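# SYNTHETIC stand-in score table generated deterministically by
# scripts/make_score_tables.py; not empirically fitted values.
# Guide bases use the DNA alphabet (T for rU).
position	guide_base	target_base	score
1	A	C	0.5621
1	A	G	0.715
1	A	T	0.4494
1	C	A	0.6101
1	C	G	0.4723
1	C	T	0.7797
1	G	A	0.8635
1	G	C	0.4345
1	G	T	0.9084
1	T	A	0.4707
1	T	C	0.8207
1	T	G	0.6597
2	A	C	0.5105
2	A	G	0.7129
2	A	T	0.4379
2	C	A	0.5977
2	C	G	0.4806
2	C	T	0.7495
2	G	A	0.8646
2	G	C	0.4401
2	G	T	0.9137
2	T	A	0.4769
2	T	C	0.8013
2	T	G	0.6666
3	A	C	0.5219
3	A	G	0.685
3	A	T	0.4447
3	C	A	0.571
3	C	G	0.4845
3	C	T	0.6947
3	G	A	0.8202
3	G	C	0.4315
3	G	T	0.8396
3	T	A	0.4538
3	T	C	0.7836
3	T	G	0.6154
4	A	C	0.5017
4	A	G	0.6704
4	A	T	0.4261
4	C	A	0.5597
4	C	G	0.4428
4	C	T	0.6988
4	G	A	0.7771
4	G	C	0.3938
4	G	T	0.8188
4	T	A	0.4687
4	T	C	0.7176
4	T	G	0.5938
5	A	C	0.4683
5	A	G	0.6023
5	A	T	0.4145
5	C	A	0.5568
5	C	G	0.439
5	C	T	0.6936
5	G	A	0.7505
5	G	C	0.4261
5	G	T	0.8304
5	T	A	0.4701
5	T	C	0.7102
5	T	G	0.5566
6	A	C	0.4856
6	A	G	0.5733
6	A	T	0.3772
6	C	A	0.5172
6	C	G	0.4254
6	C	T	0.6217
6	G	A	0.74
6	G	C	0.3896
6	G	T	0.794
6	T	A	0.4049
6	T	C	0.7131
6	T	G	0.5537
7	A	C	0.4624
7	A	G	0.5471
7	A	T	0.3581
7	C	A	0.5182
7	C	G	0.4273
7	C	T	0.6284
7	G	A	0.6877
7	G	C	0.3789
7	G	T	0.7444
7	T	A	0.4275
7	T	C	0.6541
7	T	G	0.5637
8	A	C	0.426
8	A	G	0.5399
8	A	T	0.3744
8	C	A	0.4974
8	C	G	0.3695
8	C	T	0.5625
8	G	A	0.6542
8	G	C	0.3485
8	G	T	0.7289
8	T	A	0.3887
8	T	C	0.6094
8	T	G	0.479
9	A	C	0.4073
9	A	G	0.5146
9	A	T	0.3151
9	C	A	0.4603
9	C	G	0.385
9	C	T	0.5781
9	G	A	0.6527
9	G	C	0.3595
9	G	T	0.6923
9	T	A	0.3757
9	T	C	0.5748
9	T	G	0.5003
10	A	C	0.4133
10	A	G	0.4991
10	A	T	0.2845
10	C	A	0.4227
10	C	G	0.3525
10	C	T	0.507
10	G	A	0.5728
10	G	C	0.2863
10	G	T	0.6371
10	T	A	0.3516
10	T	C	0.5546
10	T	G	0.4607
11	A	C	0.3405
11	A	G	0.4828
11	A	T	0.3018
11	C	A	0.3817
11	C	G	0.3292
11	C	T	0.4732
11	G	A	0.5269
11	G	C	0.2702
11	G	T	0.5802
11	T	A	0.3331
11	T	C	0.5161
11	T	G	0.4373
12	A	C	0.3409
12	A	G	0.4188
12	A	T	0.2883
12	C	A	0.3439
12	C	G	0.3116
12	C	T	0.4836
12	G	A	0.515
12	G	C	0.2781
12	G	T	0.5713
12	T	A	0.2896
12	T	C	0.4718
12	T	G	0.3765
13	A	C	0.2815
13	A	G	0.3779
13	A	T	0.2586
13	C	A	0.3456
13	C	G	0.3036
13	C	T	0.4016
13	G	A	0.4767
13	G	C	0.2634
13	G	T	0.5123
13	T	A	0.298
13	T	C	0.4589
13	T	G	0.3659
14	A	C	0.297
14	A	G	0.3668
14	A	T	0.2299
14	C	A	0.2993
14	C	G	0.2418
14	C	T	0.3667
14	G	A	0.4623
14	G	C	0.2408
14	G	T	0.4892
14	T	A	0.2644
14	T	C	0.3872
14	T	G	0.3364
15	A	C	0.2754
15	A	G	0.3317
15	A	T	0.2097
15	C	A	0.2534
15	C	G	0.2513
15	C	T	0.3561
15	G	A	0.3693
15	G	C	0.1802
15	G	T	0.4123
15	T	A	0.2164
15	T	C	0.356
15	T	G	0.3032
16	A	C	0.2048
16	A	G	0.2653
16	A	T	0.1819
16	C	A	0.271
16	C	G	0.1893
16	C	T	0.327
16	G	A	0.3332
16	G	C	0.1801
16	G	T	0.3629
16	T	A	0.2328
16	T	C	0.3321
16	T	G	0.2439
17	A	C	0.2239
17	A	G	0.2767
17	A	T	0.1893
17	C	A	0.2186
17	C	G	0.1823
17	C	T	0.2864
17	G	A	0.2785
17	G	C	0.1767
17	G	T	0.2958
17	T	A	0.1503
17	T	C	0.2696
17	T	G	0.2431
18	A	C	0.1545
18	A	G	0.2278
18	A	T	0.1165
18	C	A	0.1625
18	C	G	0.1547
18	C	T	0.2089
18	G	A	0.2723
18	G	C	0.1363
18	G	T	0.2489
18	T	A	0.1746
18	T	C	0.2445
18	T	G	0.1726
19	A	C	0.1384
19	A	G	0.2031
19	A	T	0.1354
19	C	A	0.1378
19	C	G	0.1528
19	C	T	0.2163
19	G	A	0.2415
19	G	C	0.1388
19	G	T	0.2448
19	T	A	0.1391
19	T	C	0.2304
19	T	G	0.1944
20	A	C	0.1334
20	A	G	0.1392
20	A	T	0.1193
20	C	A	0.1434
20	C	G	0.118
20	C	T	0.1519
20	G	A	0.1713
20	G	C	0.0682
20	G	T	0.1607
20	T	A	0.095
20	T	C	0.1347
20	T	G	0.1585
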