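molecule,medium,center_cm1
urea,milk,1457
urea,milk,1156
urea,aqueous,1461
urea,aqueous,1160
bhb,milk,2926
bhb,milk,1554
bhb,milk,1405
bhb,milk,1316
bhb,milk,1077
bhb,aqueous,2981
bhb,aqueous,1559
bhb,aqueous,1404
bhb,aqueous,1311
bhb,aqueous,1269
bhb,aqueous,1207
bhb,aqueous,1130
bhb,aqueous,1060
bhb,aqueous,948
acetone,milk,1690
acetone,milk,1414
acetone,milk,1373
acetone,milk,1239
acetone,aqueous,1689
acetone,aqueous,1424
acetone,aqueous,1370
acetone,aqueous,1239
acetone,aqueous,1096
citrate,milk,2926
citrate,milk,1557
citrate,milk,1394
citrate,milk,1248
citrate,milk,1078
citrate,aqueous,2923
citrate,aqueous,1581
citrate,aqueous,1566
citrate,aqueous,1390
citrate,aqueous,1288
citrate,aqueous,1093
acetate,milk,1551
acetate,milk,1414
acetate,aqueous,1554
acetate,aqueous,1416
acetate,aqueous,1348
acetate,aqueous,1060
acetate,aqueous,1021
acetate,aqueous,933
phosphate,milk,1156
phosphate,milk,1077
phosphate,milk,940
phosphate,aqueous,1261
phosphate,aqueous,1236
phosphate,aqueous,1160
phosphate,aqueous,1077
phosphate,aqueous,941
ammonium,milk,1457
ammonium,aqueous,1454
linoleic_acid,milk,3012
linoleic_acid,milk,2927
linoleic_acid,milk,2857
linoleic_acid,milk,1705
linoleic_acid,milk,1581
linoleic_acid,milk,1554
linoleic_acid,milk,1458
linoleic_acid,milk,1408
linoleic_acid,milk,987
linoleic_acid,aqueous,3011
linoleic_acid,aqueous,2929
linoleic_acid,aqueous,2861
linoleic_acid,aqueous,1597
linoleic_acid,aqueous,1554
linoleic_acid,aqueous,1458
linoleic_acid,aqueous,1405
creatine,milk,1538
creatine,milk,1396
creatine,milk,1311
creatine,milk,1106
creatine,milk,980
creatine,aqueous,2950
creatine,aqueous,2835
creatine,aqueous,1538
creatine,aqueous,1431
creatine,aqueous,1396
creatine,aqueous,1307
creatine,aqueous,1168
creatine,aqueous,1107
creatine,aqueous,1049
creatine,aqueous,976
histamine,milk,3012
histamine,milk,2857
histamine,milk,1581
histamine,milk,1457
histamine,milk,1315
histamine,milk,1033
histamine,milk,987
histamine,aqueous,3008
histamine,aqueous,2888
histamine,aqueous,1573
histamine,aqueous,1488
histamine,aqueous,1310
histamine,aqueous,1033
histamine,aqueous,987
histamine,aqueous,941
orotic_acid,milk,1700
orotic_acid,milk,1500
orotic_acid,milk,1377
orotic_acid,milk,1033
orotic_acid,aqueous,1700
orotic_acid,aqueous,1497
orotic_acid,aqueous,1377
orotic_acid,aqueous,1014
hippuric_acid,milk,1581
hippuric_acid,milk,1400
hippuric_acid,milk,1307
hippuric_acid,aqueous,1584
hippuric_acid,aqueous,1489
hippuric_acid,aqueous,1396
hippuric_acid,aqueous,1301
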