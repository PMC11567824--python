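participant_id,age,gender,education,ses,depression,loneliness,social_network,hearing_handicap,exercise,tinnitus,stroke,diabetes,hypertension,smoking,family_history,subjective_memory,visual_working_memory,cognitive_flexibility,model_based_index,wm_trait,flex_trait,mb_trait
P00001,50,cis_female,3,7,17,43,6,3,42,0,0,0,0,0,0,0,0.2796086602,0.9084087533,-0.02553048288,-0.04952348318,0.9194446222,0.9491778526
P00002,37,cis_male,2,4,20,12,19,3,52,0,0,0,0,0,0,1,1.51123373,-0.1857137329,0.2564660766,-1.345595229,-0.2195560145,0.1460319208
P00003,44,cis_female,3,9,42,31,17,3,9,1,0,0,1,0,1,1,-0.4513770661,-0.3225673279,0.336422655,0.7197121953,-0.3620229995,-0.08169000891
P00004,40,cis_female,4,7,25,0,22,0,25,0,0,0,0,0,0,0,1.107998695,0.4884390839,-0.09700111353,-0.9212602998,0.482248854,1.152731209
P00005,23,cis_female,3,9,24,52,15,6,60,0,0,1,0,1,1,0,1.229424258,-0.3417092924,0.4815361087,-1.049039643,-0.3819501192,-0.4949832783
P00006,68,cis_male,2,4,26,12,20,0,43,0,0,0,0,1,0,0,-0.09261253304,-0.01748118644,-0.3999389836,0.3421747564,-0.04442299238,2.015519459
P00007,55,cis_female,3,6,17,34,21,0,74,0,0,0,0,0,0,0,-1.260244038,0.3196596881,0.09739094916,1.570904375,0.3065465523,0.5990890137
P00008,40,cis_male,1,6,0,10,15,0,22,0,0,0,0,0,0,0,0.5391606927,-0.5779363218,0.5043588729,-0.3226569748,-0.6278665867,-0.5599841073
P00009,45,cis_female,3,6,7,19,23,0,16,1,0,0,0,0,0,0,0.05088160844,-1.040086779,-0.4303068843,0.1911720633,-1.108973293,2.102009365
P00010,44,cis_female,1,8,19,10,16,0,32,0,0,1,1,1,0,0,0.1047670021,0.5592539289,0.5347720559,0.1344670336,0.5559683457,-0.6466029805
P00011,40,cis_female,4,8,15,0,20,7,9,0,0,0,0,0,1,0,2.313446426,-1.715463832,0.5937871369,-2.189784937,-1.812052613,-0.8146820605
P00012,60,cis_female,4,7,15,48,9,2,37,1,0,0,0,0,1,0,1.39239792,-1.847221599,0.6957306626,-1.220541152,-1.949214752,-1.105024354
P00013,60,cis_female,3,8,12,32,14,12,0,0,0,0,0,0,0,1,0.1931863618,-0.3839392062,0.4730322897,0.04142099492,-0.4259121978,-0.4707638068
P00014,27,cis_male,3,5,0,36,14,0,34,0,0,0,0,0,0,0,2.318455991,0.2035867211,0.2281064985,-2.195056635,0.1857125643,0.2268019835
P00015,48,cis_female,2,6,13,0,17,0,66,0,0,0,0,0,0,0,1.925712314,-0.9595075938,0.697163233,-1.781762042,-1.025088952,-1.109104415
P00016,47,cis_female,2,3,0,0,17,8,19,0,0,0,0,1,0,1,-0.2684388159,0.4625561836,0.567854568,0.5272014198,0.4553043023,-0.7408242897
P00017,83,cis_female,3,3,0,3,23,7,0,0,0,0,0,0,0,1,-0.3651269133,0.737702826,0.6054786826,0.6289488706,0.7417367674,-0.8479804005
P00018,47,cis_female,2,5,21,13,8,11,44,1,0,0,0,0,0,1,-0.4114631657,-1.195369619,0.1625076385,0.6777097387,-1.270625444,0.4136321265
P00019,49,cis_male,3,6,19,27,20,0,39,0,0,0,0,0,0,0,0.1486993999,0.5488043226,0.2417836992,0.08823580553,0.5450901229,0.1878483589
P00020,22,cis_female,3,5,18,37,10,0,28,0,0,0,0,1,0,1,0.926677171,-0.5034123182,0.4487300004,-0.7304508487,-0.5502857961,-0.4015491863
P00021,29,cis_female,5,5,27,32,29,0,35,1,0,0,0,0,0,0,0.358881902,0.1916333236,0.3980333853,-0.1329448192,0.1732688685,-0.2571616794
P00022,44,cis_male,3,3,10,15,23,6,11,0,0,0,0,0,0,1,0.8518753791,0.7151042731,0.4099605703,-0.651734938,0.7182112788,-0.2911311368
P00023,45,cis_male,3,8,26,37,18,15,67,1,0,1,0,1,0,1,-0.8012017892,1.922376476,0.2187885056,1.087842035,1.975002748,0.253340279
P00024,62,cis_male,3,9,25,25,20,17,74,0,0,0,0,0,0,0,1.064479935,-1.545199529,0.2453329283,-0.8754643546,-1.634804496,0.1777399061
P00025,55,cis_female,5,6,18,25,25,7,52,1,0,0,0,1,0,0,1.097999151,-0.3837122035,0.4897644937,-0.910737515,-0.425675884,-0.5184182944
P00026,48,cis_male,2,6,14,0,18,0,7,1,0,0,0,0,0,0,-0.686199621,1.701532022,-0.03793239114,0.9668222014,1.745099811,0.984499355
P00027,37,cis_female,3,8,19,22,11,4,54,0,0,0,0,0,0,0,-0.4650021341,0.1003342786,-0.1100627089,0.7340502159,0.07822496648,1.189931547
P00028,49,cis_female,1,7,1,21,5,3,58,1,0,0,0,0,0,1,-2.099856895,0.4236407131,-0.1142543991,2.454451266,0.4147926172,1.201869774
P00029,55,cis_male,3,8,27,53,16,13,23,1,1,0,0,1,1,1,-0.01113456813,0.9855813581,0.1973443992,0.2564333317,0.999782653,0.3144145945
P00030,54,cis_male,3,7,48,48,18,0,63,0,0,0,0,1,0,1,-0.03599097555,-0.6760683223,0.4405772005,0.2825903888,-0.7300237149,-0.3783294419
P00031,41,cis_female,4,8,25,29,21,8,59,0,0,0,0,0,0,0,0.2127664293,-0.2640929561,1.226811873,0.02081637031,-0.3011501561,-2.617580801
P00032,42,cis_female,2,7,29,35,13,4,24,0,0,0,0,1,0,1,-0.8670846175,0.3932018774,0.008638847923,1.157172284,0.3831052571,0.8518612078
P00033,53,cis_female,2,5,0,25,0,0,-0,0,0,0,0,0,0,1,-0.4898014431,0.4762875877,0.06819498842,0.7601471868,0.4695989341,0.6822411526
P00034,21,cis_male,2,6,20,22,16,8,24,0,0,0,1,0,0,0,1.101041714,-0.5820382648,0.2456571511,-0.9139392843,-0.6321367811,0.1768164969
P00035,62,cis_female,2,3,25,34,9,4,2,0,0,1,0,0,0,1,-0.4873677116,2.965616469,-0.3317904251,0.7575861066,3.06103382,1.821427596
P00036,45,cis_female,5,8,28,60,20,0,31,1,0,0,0,1,1,1,0.1844433208,0.3726827473,-0.182868806,0.05062152898,0.3617444839,1.397288405
P00037,38,cis_male,1,4,26,25,14,1,34,0,0,0,0,0,1,1,0.5908848418,0.5787290303,0.2309614935,-0.3770876696,0.5762422668,0.2186707578
P00038,47,cis_female,2,7,12,12,17,7,39,0,0,0,1,0,1,0,1.339304254,-0.7103298026,0.009104954585,-1.164669278,-0.7656905149,0.8505337034
P00039,72,cis_male,3,6,18,16,17,8,50,0,0,0,0,0,0,1,-1.086705424,1.348103067,0.5410185437,1.388285087,1.37717409,-0.6643934149
P00040,48,cis_female,2,3,9,21,14,4,24,1,0,0,0,0,0,0,-0.4745741025,0.3904897947,-0.035523285,0.7441230523,0.3802819316,0.9776380522
P00041,38,cis_female,3,8,42,50,24,8,44,0,0,0,1,0,0,1,-0.8209834467,0.279150423,0.5640522745,1.108658798,0.264375699,-0.7299950918
P00042,42,cis_female,3,8,13,45,13,6,57,1,0,1,1,0,0,0,-0.162049581,0.208486828,0.7010710453,0.4152452046,0.1908136612,-1.120234138
P00043,43,cis_male,4,7,19,13,12,0,46,0,0,0,0,0,0,0,0.08724221555,-0.6942472865,0.7009081594,0.1529088315,-0.7489483344,-1.119770227
P00044,36,cis_male,5,8,2,28,13,8,43,0,0,0,0,1,0,0,2.0415681,0.4819362342,0.5135839244,-1.90368016,0.4754792738,-0.5862576996
P00045,63,cis_male,1,1,0,13,7,5,30,0,0,0,0,0,0,1,0.4721159656,0.7843179084,0.003594151075,-0.2521040292,0.7902638832,0.8662288573
P00046,49,cis_female,3,7,5,22,21,11,27,0,0,0,0,0,0,0,0.5487339257,-1.462246624,0.4629670999,-0.332731142,-1.548449071,-0.4420974418
P00047,49,cis_female,3,7,34,13,14,1,47,0,0,0,0,0,0,0,-1.201480332,0.468256908,0.1106260169,1.509065768,0.4612388561,0.5613946146
P00048,82,cis_male,2,8,12,31,12,6,54,0,0,0,0,0,1,0,-0.1897213409,0.4849306029,0.6957307063,0.4443649319,0.478596464,-1.105024479
P00049,27,cis_male,4,3,38,30,23,0,0,0,0,0,0,1,1,1,0.4370255084,-1.484671181,1.089588317,-0.21517741,-1.571793427,-2.226758512
P00050,60,cis_female,2,7,18,0,21,10,70,0,0,0,0,0,0,0,-0.07421068285,-1.348214423,0.6547808221,0.3228100011,-1.429739557,-0.9883963432
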