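band_nm,functionality
1348,Self-organisation; germination; storage changes; viability
1360,Germination; water activity and storage changes; hardness; viability; texture
1373,Water vapour band; proton hydration; sucrose-content indicator; viability; water activity; texture
1385,Hydration of ions; pH modelling; firmness and texture
1391,Drying and dehydration; expulsion of cellular water; damage and stress; vitamin C content
1410,Moisture content; water activity; seed viability; firmness; vitamin C content
1428,Protein hydration and folding; water activity; damage and defects
1435,Phase transition; carbohydrate-water interaction; hardness; viability
1441,Preservation during desiccation stress
1447,Water activity; biotic/abiotic stress indicator; preservation; damage
1459,Water activity; biotic/abiotic stress indicator; preservation; damage
1466,Protein-water interaction
1478,Semi-crystalline water associated with cellulose and other polymers; stiffness
1484,Associated with cellulose and other polymers; tissue preservation; damage
1490,Water activity; biotic/abiotic stress indicator; preservation; damage
1503,Skin disease; defects in minerals; structural defects in starch
1521,Structural water; water-polymer interaction; fresh/thawed discrimination; mechanical damage
1528,Structural water; water-polymer interaction; fresh/thawed discrimination; mechanical damage
1534,Structural water; drying indicator; water-protein interaction; sorbed-water clustering
1559,Structural water; polymer- and sugar-associated; membrane structure; crystallinity; tissue preservation
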