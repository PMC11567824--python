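participant_id,form,run_index,completion_time
P00001,A,1,35.71650251
P00001,B,1,400
P00001,A,2,34.07741783
P00001,B,2,400
P00001,A,3,36.87107618
P00001,B,3,400
P00002,A,1,28.65848451
P00002,B,1,53.77803924
P00002,A,2,23.59219184
P00002,B,2,61.55887375
P00002,A,3,21.29656288
P00002,B,3,54.28644576
P00003,A,1,24.49737481
P00003,B,1,51.34568649
P00003,A,2,23.09850966
P00003,B,2,68.34774265
P00003,A,3,27.63736309
P00003,B,3,54.26018197
P00004,A,1,30.35399334
P00004,B,1,67.9520399
P00004,A,2,34.26676176
P00004,B,2,60.45310367
P00004,A,3,31.73267091
P00004,B,3,68.19789019
P00005,A,1,34.98971345
P00005,B,1,44.10538664
P00005,A,2,27.13652832
P00005,B,2,45.76751413
P00005,A,3,24.20417131
P00005,B,3,53.6072759
P00006,A,1,32.17793646
P00006,B,1,60.94554963
P00006,A,2,28.33209915
P00006,B,2,60.96933101
P00006,A,3,21.41102636
P00006,B,3,62.69251713
P00007,A,1,37.50044533
P00007,B,1,56.24394559
P00007,A,2,29.30990125
P00007,B,2,421.6648704
P00007,A,3,37.39031072
P00007,B,3,68.37959542
P00008,A,1,28.36884224
P00008,B,1,45.47841296
P00008,A,2,23.94039977
P00008,B,2,44.86137794
P00008,A,3,25.01321344
P00008,B,3,54.27272062
P00009,A,1,23.84624134
P00009,B,1,40.41118552
P00009,A,2,21.87772375
P00009,B,2,49.71766349
P00009,A,3,26.19822123
P00009,B,3,48.87098419
P00010,A,1,30.26304788
P00010,B,1,55.55909892
P00010,A,2,30.90191472
P00010,B,2,79.66631363
P00010,A,3,30.33696915
P00010,B,3,67.68186569
P00011,A,1,18.06012752
P00011,B,1,38.64718169
P00011,A,2,17.61936816
P00011,B,2,33.22506264
P00011,A,3,21.83796416
P00011,B,3,34.84054159
P00012,A,1,18.98013674
P00012,B,1,35.1097277
P00012,A,2,18.41754223
P00012,B,2,35.96218249
P00012,A,3,14.83958988
P00012,B,3,41.63736735
P00013,A,1,24.94418754
P00013,B,1,55.76320689
P00013,A,2,25.15282045
P00013,B,2,55.57767491
P00013,A,3,33.4319676
P00013,B,3,43.90200231
P00014,A,1,31.46938632
P00014,B,1,64.20517814
P00014,A,2,27.61545537
P00014,B,2,72.13981514
P00014,A,3,31.2073222
P00014,B,3,66.70456285
P00015,A,1,23.50762088
P00015,B,1,45.12976028
P00015,A,2,22.18637571
P00015,B,2,43.32438687
P00015,A,3,20.52732963
P00015,B,3,41.99177485
P00016,A,1,31.29305047
P00016,B,1,64.16461296
P00016,A,2,30.79385233
P00016,B,2,76.73300436
P00016,A,3,33.78611921
P00016,B,3,74.75982918
P00017,A,1,34.05396719
P00017,B,1,59.39165148
P00017,A,2,29.70272176
P00017,B,2,63.98703638
P00017,A,3,40.88938937
P00017,B,3,76.04367653
P00018,A,1,19.84206449
P00018,B,1,36.00084602
P00018,A,2,21.64115842
P00018,B,2,44.92115263
P00018,A,3,25.37028041
P00018,B,3,43.22960635
P00019,A,1,33.69432626
P00019,B,1,62.15435197
P00019,A,2,35.94794328
P00019,B,2,74.30899827
P00019,A,3,31.63649381
P00019,B,3,59.10073164
P00020,A,1,24.32484108
P00020,B,1,43.09434243
P00020,A,2,25.41088983
P00020,B,2,54.96613938
P00020,A,3,24.74137012
P00020,B,3,49.90286153
P00021,A,1,36.71980458
P00021,B,1,66.53616376
P00021,A,2,32.26415172
P00021,B,2,51.37819117
P00021,A,3,27.66126523
P00021,B,3,69.23231099
P00022,A,1,34.77203778
P00022,B,1,62.90239172
P00022,A,2,40.34811936
P00022,B,2,66.82580388
P00022,A,3,39.83617389
P00022,B,3,71.14625895
P00023,A,1,54.65335165
P00023,B,1,103.0586698
P00023,A,2,42.02441697
P00023,B,2,121.510106
P00023,A,3,46.89775564
P00023,B,3,99.53367773
P00024,A,1,17.27762445
P00024,B,1,48.69770482
P00024,A,2,18.79984689
P00024,B,2,28.39338657
P00024,A,3,22.37857301
P00024,B,3,31.85551289
P00025,A,1,21.22504775
P00025,B,1,54.96740183
P00025,A,2,23.55449504
P00025,B,2,58.61978332
P00025,A,3,21.62247422
P00025,B,3,66.18359257
P00026,A,1,42.06528056
P00026,B,1,115.4611532
P00026,A,2,51.78991476
P00026,B,2,80.58495798
P00026,A,3,53.47277398
P00026,B,3,108.4147313
P00027,A,1,26.8126521
P00027,B,1,80.15810115
P00027,A,2,27.97639181
P00027,B,2,67.20827209
P00027,A,3,29.93860211
P00027,B,3,65.28859313
P00028,A,1,43.09947001
P00028,B,1,63.71595949
P00028,A,2,31.41279754
P00028,B,2,80.34457246
P00028,A,3,39.09824256
P00028,B,3,97.93181091
P00029,A,1,43.953582
P00029,B,1,87.94983691
P00029,A,2,39.58944462
P00029,B,2,92.57879413
P00029,A,3,38.72264162
P00029,B,3,70.37102024
P00030,A,1,28.11787138
P00030,B,1,50.93746595
P00030,A,2,29.93218734
P00030,B,2,53.173532
P00030,A,3,26.81665115
P00030,B,3,39.25736433
P00031,A,1,30.80109046
P00031,B,1,58.38956572
P00031,A,2,29.56272989
P00031,B,2,42.05453881
P00031,A,3,27.45306995
P00031,B,3,47.56873676
P00032,A,1,41.31744108
P00032,B,1,60.13732707
P00032,A,2,32.21130151
P00032,B,2,81.24176832
P00032,A,3,33.30285697
P00032,B,3,59.77613768
P00033,A,1,34.87344941
P00033,B,1,58.08565341
P00033,A,2,26.25127283
P00033,B,2,86.45928198
P00033,A,3,38.97216203
P00033,B,3,64.21848017
P00034,A,1,27.05160868
P00034,B,1,46.8887806
P00034,A,2,23.65252462
P00034,B,2,53.24769274
P00034,A,3,22.28800385
P00034,B,3,42.66464207
P00035,A,1,55.10280868
P00035,B,1,160.973746
P00035,A,2,56.94512951
P00035,B,2,156.6267572
P00035,A,3,66.65838624
P00035,B,3,136.7319426
P00036,A,1,32.58767068
P00036,B,1,72.13929766
P00036,A,2,31.37443184
P00036,B,2,62.97923723
P00036,A,3,33.49183395
P00036,B,3,66.38740429
P00037,A,1,42.32882805
P00037,B,1,55.93133408
P00037,A,2,37.7684481
P00037,B,2,87.61904223
P00037,A,3,31.44546185
P00037,B,3,69.46629832
P00038,A,1,24.53359985
P00038,B,1,46.09379627
P00038,A,2,27.12282414
P00038,B,2,36.96211178
P00038,A,3,25.62537781
P00038,B,3,41.96930579
P00039,A,1,40.89254024
P00039,B,1,96.02149073
P00039,A,2,42.27539846
P00039,B,2,87.42133254
P00039,A,3,36.3349107
P00039,B,3,86.725853
P00040,A,1,39.37934208
P00040,B,1,76.48556729
P00040,A,2,32.02956287
P00040,B,2,82.22426635
P00040,A,3,31.8853317
P00040,B,3,63.72075021
P00041,A,1,26.31522576
P00041,B,1,71.50762069
P00041,A,2,33.6544743
P00041,B,2,60.70235756
P00041,A,3,35.06403169
P00041,B,3,70.81576647
P00042,A,1,34.98626506
P00042,B,1,68.17529821
P00042,A,2,30.00867381
P00042,B,2,70.33601807
P00042,A,3,36.4221848
P00042,B,3,91.58676034
P00043,A,1,31.96527116
P00043,B,1,59.66054883
P00043,A,2,28.15584576
P00043,B,2,55.92933466
P00043,A,3,24.90899988
P00043,B,3,48.45616666
P00044,A,1,34.29411992
P00044,B,1,73.0476314
P00044,A,2,36.28630748
P00044,B,2,70.042649
P00044,A,3,230.5889205
P00044,B,3,79.4177242
P00045,A,1,41.72702567
P00045,B,1,68.21643681
P00045,A,2,50.02076174
P00045,B,2,81.51790857
P00045,A,3,33.47277232
P00045,B,3,77.86448259
P00046,A,1,19.08167633
P00046,B,1,43.21896399
P00046,A,2,22.99659581
P00046,B,2,35.40613326
P00046,A,3,22.78564162
P00046,B,3,39.0000515
P00047,A,1,30.71370896
P00047,B,1,61.81128242
P00047,A,2,34.24516656
P00047,B,2,61.8610733
P00047,A,3,31.4300627
P00047,B,3,64.43134665
P00048,A,1,217.7440349
P00048,B,1,78.05485371
P00048,A,2,29.36468248
P00048,B,2,59.71213107
P00048,A,3,47.94115123
P00048,B,3,95.34923403
P00049,A,1,19.19751619
P00049,B,1,29.51241842
P00049,A,2,19.32524828
P00049,B,2,46.58895487
P00049,A,3,16.8203968
P00049,B,3,43.70973946
P00050,A,1,19.17887664
P00050,B,1,31.23621607
P00050,A,2,23.74039213
P00050,B,2,35.06756913
P00050,A,3,18.74575349
P00050,B,3,39.22141057
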