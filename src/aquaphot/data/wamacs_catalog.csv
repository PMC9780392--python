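label,lo_nm,hi_nm,nominal_nm,assignment
C1,1336,1348,,Antisymmetric OH stretch of water (nu3)
C2,1360,1366,,Water solvation shell OH-(H2O)(1;2;4); water vapour; proton hydrates
C3,1370,1376,,Combination of symmetric and asymmetric OH stretch (nu1+nu3); water vapour; proton hydrates
C4,1380,1388,,Water solvation shell OH-(H2O)(1;4); superoxide hydrate; water vapour; proton hydrates
C5,1396,1403,,Confined single water molecules (trapped water); free OH trapped in hydrophobic interior
C5,1404,1414,,Free water molecules
C6,1421,1430,,Water hydration band; H-OH bend hydroxide; condensed surface water layers
C7,1432,1444,,Non-bonded O-H stretching first overtone; OH bending overtone of water dimer
C8,1448,1454,,Water solvation shell OH-(H2O)(4;5)
C9,1458,1468,,Water molecules with two hydrogen bonds
C10,1472,1482,,Water molecules with three hydrogen bonds
C11,1482,1495,,Water molecules with four hydrogen bonds
C12,1506,1516,,Strongly bound water; symmetric stretch and doubly degenerate bend (nu1;nu2)
Ci,,,1503,Strongly bound water; intermolecular hydrogen bonds; crystal-structure water
Cj,,,1528,Strongly bound water; intermolecular hydrogen bonds
Ck,,,1534,Hydrogen-bonded hydroxyl groups; bound O-H stretch first overtone
Cl,,,1559,Ionic bound water first overtone; strongly hydrogen-bonded water; crystalline ice
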