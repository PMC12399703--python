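t,S,I,R
0.0,1000.257302210934,-0.3210486329130189,6.40422650443282
1.0,999.4257796402921,-3.8226207791517415,3.7050991278737184
2.0,1010.4616528388151,11.823274822417869,-6.811469936709209
3.0,983.3049839603009,-2.62744145523779,0.8487579525752069
4.0,970.472765526041,3.3324087774282583,-11.702508161713725
5.0,982.9886125641142,2.998201967834807,-1.915079471248121
6.0,989.2389632979041,23.3041015195054,0.7130276113182155
7.0,990.9354136759362,12.93570113206955,6.656673863555136
8.0,974.5118474597812,30.586927408157443,-2.558942567349769
9.0,938.7429715568371,39.970768314473546,9.693699344132273
10.0,912.273924235506,64.13696311012774,9.808924971117012
11.0,891.2834192501018,99.10320276055636,20.722152151662453
12.0,829.0316787447158,137.6137964273921,33.35985709739427
13.0,784.3094232833354,180.72335099326853,52.450119601953006
14.0,700.8229350576305,267.03599392297906,56.05749556751078
15.0,589.8076542300497,347.1118932378258,94.12401438662924
16.0,510.8972205161248,419.34340359272915,104.50056634374029
17.0,383.4411707272158,472.0678913407871,138.92795962873763
18.0,295.25256172582795,527.7846098493966,172.32907133732203
19.0,241.88772450540327,546.4488373000283,200.16566004623454
20.0,172.4477121571286,564.1088358077125,264.77475925729925
21.0,127.44757046870825,582.1863128294417,286.1109802572911
22.0,115.12411247590455,584.0975927456564,336.1501596655275
23.0,52.87526854668313,555.5438003454781,376.90298395173625
24.0,67.08661277522484,527.7911086132817,427.2029375561221
25.0,30.736384589111754,503.1705426641432,455.62398270959983
26.0,34.76366652485362,503.98024890863053,483.655748466346
27.0,20.753167263013452,453.7433649659312,504.48443064061274
28.0,8.912629755124938,437.4817959069508,552.9445457058682
29.0,30.542299633299784,397.85104461152514,593.8972605614233
30.0,11.584651404618937,396.2182829766312,600.7394128572828
31.0,4.67108747961061,359.0875048947298,641.6989592665178
32.0,11.730004511672238,327.9889871731998,642.6236187002809
33.0,-5.404358523243458,317.3112613357404,689.001853869935
34.0,5.7610578768629335,281.1759970073359,709.4067721334804
35.0,-6.374380726633354,265.60412370835434,727.045815155941
36.0,-16.86586253127078,258.56232404528646,733.8494143618058
37.0,6.075750210516158,237.01251279308582,759.2686626594069
38.0,11.38391389611571,214.31598679923513,787.8679413858537
39.0,11.251591533475587,215.475197564923,800.6201152252213
40.0,11.486761894725682,201.572200655544,804.0136425800031
41.0,-10.978443698372853,178.77708744751354,808.8880203388242
42.0,-11.212169572509495,170.55881602597506,823.3249692290332
43.0,-7.517725654219557,146.19112831124087,843.2827129592368
44.0,6.164518035258802,159.24397489776862,851.2636545711027
45.0,12.820702648292865,150.14510761041115,872.9768919626457
46.0,-21.403549694396805,139.1727588880145,874.2607890181325
47.0,6.35352784858026,121.979944736648,883.4440867233748
48.0,5.192526845874194,106.6387409029063,868.7573883845964
49.0,0.8056687505941154,94.69163497864231,906.1778646318606
50.0,-1.0845315590541373,96.5702800464548,893.9652804576135
51.0,-3.384532673731121,89.09900109039012,894.2102244448578
52.0,4.65596512530708,82.07342034997035,903.3595450831382
53.0,-22.398088683768332,82.59619752198022,917.9742434571796
54.0,-3.773994833380706,69.81994786242369,944.4571759490569
55.0,0.9758189423863994,68.12210143167539,916.3995338684728
56.0,17.900137322786666,71.83976514920165,946.5777166960669
57.0,1.8609609212045366,67.55249579121966,943.9392868388821
58.0,7.4776553897843065,52.87615875461531,929.5172675696874
59.0,11.599429567828087,31.332081538559745,945.608069292966
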