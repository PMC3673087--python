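alpha_deg,height_cm,distance_m,n_pixels
10,210,3.0,120456
10,215,3.0,122547
10,220,3.0,124754
10,225,3.0,126354
10,230,3.0,128452
10,210,3.5,101239
10,215,3.5,102569
10,220,3.5,103698
10,225,3.5,103967
10,230,3.5,104693
10,210,4.0,71895
10,215,4.0,72698
10,220,4.0,74147
10,225,4.0,74236
10,230,4.0,75100
10,210,4.5,55326
10,215,4.5,56314
10,220,4.5,57259
10,225,4.5,58965
10,230,4.5,59996
10,210,5.0,37989
10,215,5.0,38654
10,220,5.0,39541
10,225,5.0,39987
10,230,5.0,41253
20,210,3.0,119872
20,215,3.0,121622
20,220,3.0,123682
20,225,3.0,125462
20,230,3.0,127442
20,210,3.5,98589
20,215,3.5,99745
20,220,3.5,100695
20,225,3.5,100885
20,230,3.5,101210
20,210,4.0,70912
20,215,4.0,71992
20,220,4.0,73245
20,225,4.0,73856
20,230,4.0,74342
20,210,4.5,54856
20,215,4.5,55123
20,220,4.5,56985
20,225,4.5,59001
20,230,4.5,59896
20,210,5.0,36552
20,215,5.0,37472
20,220,5.0,38442
20,225,5.0,39152
20,230,5.0,40232
30,210,3.0,114152
30,215,3.0,115351
30,220,3.0,116321
30,225,3.0,117244
30,230,3.0,118089
30,210,3.5,94523
30,215,3.5,95325
30,220,3.5,95986
30,225,3.5,96854
30,230,3.5,98752
30,210,4.0,68108
30,215,4.0,68812
30,220,4.0,69543
30,225,4.0,69332
30,230,4.0,70811
30,210,4.5,53865
30,215,4.5,54169
30,220,4.5,54896
30,225,4.5,55896
30,230,4.5,56987
30,210,5.0,35648
30,215,5.0,36182
30,220,5.0,36762
30,225,5.0,37421
30,230,5.0,37895
40,210,3.0,118338
40,215,3.0,118645
40,220,3.0,119078
40,225,3.0,119176
40,230,3.0,119357
40,210,3.5,94021
40,215,3.5,95685
40,220,3.5,96852
40,225,3.5,97246
40,230,3.5,98563
40,210,4.0,74594
40,215,4.0,74729
40,220,4.0,74947
40,225,4.0,74752
40,230,4.0,75219
40,210,4.5,52023
40,215,4.5,52869
40,220,4.5,53695
40,225,4.5,54754
40,230,4.5,55625
40,210,5.0,39602
40,215,5.0,40226
40,220,5.0,40713
40,225,5.0,41160
40,230,5.0,41581
50,210,3.0,121236
50,215,3.0,123568
50,220,3.0,125698
50,225,3.0,127425
50,230,3.0,129423
50,210,3.5,94865
50,215,3.5,95862
50,220,3.5,96899
50,225,3.5,97585
50,230,3.5,98865
50,210,4.0,74625
50,215,4.0,74987
50,220,4.0,75125
50,225,4.0,75012
50,230,4.0,75652
50,210,4.5,51745
50,215,4.5,51658
50,220,4.5,52896
50,225,4.5,54585
50,230,4.5,55632
50,210,5.0,39874
50,215,5.0,40325
50,220,5.0,41256
50,225,5.0,42015
50,230,5.0,42569
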