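# canonical double-gamma hemodynamic response, version 1: peak 6 s, undershoot 16 s, ratio 1/6, sampled at 10 Hz, peak-normalized
time_s,amplitude
0.0,0.00000000
0.1,0.00000043
0.2,0.00001244
0.3,0.00008551
0.4,0.00032604
0.5,0.00090031
0.6,0.00202706
0.7,0.00396434
0.8,0.00699361
0.9,0.01140341
1.0,0.01747402
1.1,0.02546401
1.2,0.03559919
1.3,0.04806414
1.4,0.06299632
1.5,0.08048257
1.6,0.10055785
1.7,0.12320583
1.8,0.14836099
1.9,0.17591211
2.0,0.20570662
2.1,0.23755562
2.2,0.27123941
2.3,0.30651314
2.4,0.34311260
2.5,0.38075975
2.6,0.41916813
2.7,0.45804784
2.8,0.49711019
2.9,0.53607181
3.0,0.57465831
3.1,0.61260747
3.2,0.64967187
3.3,0.68562106
3.4,0.72024331
3.5,0.75334682
3.6,0.78476061
3.7,0.81433500
3.8,0.84194174
3.9,0.86747388
4.0,0.89084536
4.1,0.91199037
4.2,0.93086251
4.3,0.94743388
4.4,0.96169389
4.5,0.97364815
4.6,0.98331717
4.7,0.99073509
4.8,0.99594832
4.9,0.99901428
5.0,1.00000000
5.1,0.99898094
5.2,0.99603969
5.3,0.99126477
5.4,0.98474955
5.5,0.97659114
5.6,0.96688937
5.7,0.95574592
5.8,0.94326341
5.9,0.92954463
6.0,0.91469183
6.1,0.89880611
6.2,0.88198678
6.3,0.86433094
6.4,0.84593300
6.5,0.82688433
6.6,0.80727291
6.7,0.78718313
6.8,0.76669557
6.9,0.74588679
7.0,0.72482932
7.1,0.70359147
7.2,0.68223741
7.3,0.66082708
7.4,0.63941627
7.5,0.61805664
7.6,0.59679586
7.7,0.57567762
7.8,0.55474180
7.9,0.53402461
8.0,0.51355868
8.1,0.49337326
8.2,0.47349436
8.3,0.45394489
8.4,0.43474487
8.5,0.41591156
8.6,0.39745966
8.7,0.37940146
8.8,0.36174700
8.9,0.34450426
9.0,0.32767929
9.1,0.31127639
9.2,0.29529826
9.3,0.27974611
9.4,0.26461985
9.5,0.24991818
9.6,0.23563872
9.7,0.22177817
9.8,0.20833237
9.9,0.19529643
10.0,0.18266483
10.1,0.17043150
10.2,0.15858992
10.3,0.14713318
10.4,0.13605406
10.5,0.12534509
10.6,0.11499862
10.7,0.10500688
10.8,0.09536198
10.9,0.08605603
11.0,0.07708111
11.1,0.06842934
11.2,0.06009289
11.3,0.05206402
11.4,0.04433511
11.5,0.03689863
11.6,0.02974721
11.7,0.02287362
11.8,0.01627080
11.9,0.00993185
12.0,0.00385002
12.1,-0.00198124
12.2,-0.00756833
12.3,-0.01291747
12.4,-0.01803470
12.5,-0.02292592
12.6,-0.02759685
12.7,-0.03205307
12.8,-0.03629997
12.9,-0.04034286
13.0,-0.04418685
13.1,-0.04783695
13.2,-0.05129805
13.3,-0.05457491
13.4,-0.05767218
13.5,-0.06059443
13.6,-0.06334610
13.7,-0.06593157
13.8,-0.06835512
13.9,-0.07062095
14.0,-0.07273322
14.1,-0.07469598
14.2,-0.07651326
14.3,-0.07818901
14.4,-0.07972713
14.5,-0.08113149
14.6,-0.08240589
14.7,-0.08355411
14.8,-0.08457988
14.9,-0.08548690
15.0,-0.08627882
15.1,-0.08695928
15.2,-0.08753187
15.3,-0.08800015
15.4,-0.08836765
15.5,-0.08863789
15.6,-0.08881432
15.7,-0.08890039
15.8,-0.08889949
15.9,-0.08881501
16.0,-0.08865028
16.1,-0.08840860
16.2,-0.08809324
16.3,-0.08770743
16.4,-0.08725436
16.5,-0.08673716
16.6,-0.08615896
16.7,-0.08552279
16.8,-0.08483169
16.9,-0.08408861
17.0,-0.08329646
17.1,-0.08245811
17.2,-0.08157638
17.3,-0.08065400
17.4,-0.07969369
17.5,-0.07869808
17.6,-0.07766975
17.7,-0.07661122
17.8,-0.07552495
17.9,-0.07441334
18.0,-0.07327872
18.1,-0.07212335
18.2,-0.07094943
18.3,-0.06975909
18.4,-0.06855441
18.5,-0.06733738
18.6,-0.06610993
18.7,-0.06487393
18.8,-0.06363117
18.9,-0.06238338
19.0,-0.06113222
19.1,-0.05987928
19.2,-0.05862608
19.3,-0.05737408
19.4,-0.05612468
19.5,-0.05487919
19.6,-0.05363888
19.7,-0.05240494
19.8,-0.05117851
19.9,-0.04996066
20.0,-0.04875240
20.1,-0.04755468
20.2,-0.04636839
20.3,-0.04519436
20.4,-0.04403337
20.5,-0.04288614
20.6,-0.04175335
20.7,-0.04063561
20.8,-0.03953348
20.9,-0.03844749
21.0,-0.03737810
21.1,-0.03632574
21.2,-0.03529079
21.3,-0.03427358
21.4,-0.03327441
21.5,-0.03229354
21.6,-0.03133118
21.7,-0.03038752
21.8,-0.02946269
21.9,-0.02855682
22.0,-0.02766998
22.1,-0.02680222
22.2,-0.02595357
22.3,-0.02512401
22.4,-0.02431352
22.5,-0.02352203
22.6,-0.02274947
22.7,-0.02199573
22.8,-0.02126070
22.9,-0.02054422
23.0,-0.01984614
23.1,-0.01916629
23.2,-0.01850446
23.3,-0.01786045
23.4,-0.01723405
23.5,-0.01662502
23.6,-0.01603311
23.7,-0.01545808
23.8,-0.01489965
23.9,-0.01435757
24.0,-0.01383154
24.1,-0.01332129
24.2,-0.01282653
24.3,-0.01234696
24.4,-0.01188228
24.5,-0.01143219
24.6,-0.01099639
24.7,-0.01057456
24.8,-0.01016639
24.9,-0.00977159
25.0,-0.00938983
25.1,-0.00902081
25.2,-0.00866423
25.3,-0.00831976
25.4,-0.00798711
25.5,-0.00766596
25.6,-0.00735603
25.7,-0.00705700
25.8,-0.00676859
25.9,-0.00649050
26.0,-0.00622243
26.1,-0.00596411
26.2,-0.00571525
26.3,-0.00547557
26.4,-0.00524481
26.5,-0.00502268
26.6,-0.00480893
26.7,-0.00460330
26.8,-0.00440554
26.9,-0.00421538
27.0,-0.00403260
27.1,-0.00385695
27.2,-0.00368819
27.3,-0.00352610
27.4,-0.00337045
27.5,-0.00322103
27.6,-0.00307762
27.7,-0.00294002
27.8,-0.00280802
27.9,-0.00268142
28.0,-0.00256004
28.1,-0.00244368
28.2,-0.00233217
28.3,-0.00222533
28.4,-0.00212298
28.5,-0.00202496
28.6,-0.00193112
28.7,-0.00184128
28.8,-0.00175530
28.9,-0.00167303
29.0,-0.00159434
29.1,-0.00151907
29.2,-0.00144710
29.3,-0.00137830
29.4,-0.00131254
29.5,-0.00124969
29.6,-0.00118966
29.7,-0.00113231
29.8,-0.00107754
29.9,-0.00102525
30.0,-0.00097534
30.1,-0.00092769
30.2,-0.00088223
30.3,-0.00083886
30.4,-0.00079749
30.5,-0.00075804
30.6,-0.00072042
30.7,-0.00068456
30.8,-0.00065039
30.9,-0.00061782
31.0,-0.00058679
31.1,-0.00055723
31.2,-0.00052907
31.3,-0.00050227
31.4,-0.00047674
31.5,-0.00045245
31.6,-0.00042933
31.7,-0.00040733
31.8,-0.00038640
31.9,-0.00036649
32.0,-0.00034755
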