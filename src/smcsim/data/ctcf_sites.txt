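# CTCF barrier positions on a 20,000-site (1 kb/site) lattice
0
55
201
239
516
551
666
717
806
1366
1714
1905
2050
2214
2386
2456
2586
2713
2829
3088
3315
3875
4196
4480
4593
4845
4972
5008
5131
5228
5437
5593
5626
5686
5786
5840
5895
6198
6250
6427
6602
6818
6950
7632
7898
8175
8328
8423
8646
9028
9395
9505
9571
9770
9920
10182
10231
10422
10684
10853
10912
10991
11287
11412
11570
11631
12107
12203
12388
12459
12729
13180
13499
13554
13634
13769
13930
13959
14143
14241
14315
14463
14497
14619
14650
14800
15100
15177
15321
15460
15492
15520
15620
15692
15747
15837
16245
16415
16569
16737
16844
17029
17181
17189
17254
17684
17725
17837
17885
17961
18072
18146
18261
18544
18721
18950
19184
19258
19414
19528
19570
19610
19753
19809
19999
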