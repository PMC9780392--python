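band_nm,wamacs,importance
1348,C1,2
1360,C2,3
1373,C3,3
1379,C4,4
1385,C4,4
1391,C5,4
1397,C5,4
1404,C5,2
1410,C5,3
1416,C5,1
1428,C6,3
1435,C7,1
1441,C7,1
1447,C8,5
1453,C8,1
1459,C9,3
1466,C9,1
1472,C10,1
1478,C10,4
1484,C11,2
1490,C11,2
1497,C11,2
1503,Ci,4
1509,C12,1
1521,C12,1
1528,Cj,4
1534,Ck,5
1559,Cl,4
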