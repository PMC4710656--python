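quality,site,breed,trait,c1,c2,c3,wr_printed
Best,Amboseli,Red Maasai,Body Size and Growth,6,4,3,0.27
Best,Amboseli,Red Maasai,Condition,0,4,3,0.15
Best,Amboseli,Red Maasai,Milk Production,3,4,1,0.17
Best,Amboseli,Red Maasai,Reproduction and Mothering Ability,9,4,0,0.27
Best,Amboseli,Red Maasai,Drought Tolerance,6,0,0,0.13
Best,Amboseli,Red Maasai,Disease Resistance,0,0,0,0.00
Best,Amboseli,Red Maasai,Breed Attributes,0,0,1,0.02
Best,Isinya,Red Maasai,Body Size and Growth,12,8,3,0.35
Best,Isinya,Red Maasai,Condition,0,0,0,0.00
Best,Isinya,Red Maasai,Milk Production,3,4,4,0.17
Best,Isinya,Red Maasai,Reproduction and Mothering Ability,0,4,2,0.09
Best,Isinya,Red Maasai,Drought Tolerance,9,2,0,0.17
Best,Isinya,Red Maasai,Disease Resistance,3,8,1,0.18
Best,Isinya,Red Maasai,Breed Attributes,3,0,0,0.05
Best,Amboseli,Dorper,Body Size and Growth,12,6,1,0.53
Best,Amboseli,Dorper,Condition,3,2,0,0.14
Best,Amboseli,Dorper,Milk Production,3,0,2,0.14
Best,Amboseli,Dorper,Reproduction and Mothering Ability,0,2,0,0.06
Best,Amboseli,Dorper,Drought Tolerance,0,0,0,0.00
Best,Amboseli,Dorper,Disease Resistance,0,0,0,0.00
Best,Amboseli,Dorper,Breed Attributes,0,2,3,0.14
Best,Isinya,Dorper,Body Size and Growth,18,10,2,0.71
Best,Isinya,Dorper,Condition,0,0,0,0.00
Best,Isinya,Dorper,Milk Production,0,2,4,0.14
Best,Isinya,Dorper,Reproduction and Mothering Ability,3,2,0,0.12
Best,Isinya,Dorper,Drought Tolerance,0,0,0,0.00
Best,Isinya,Dorper,Disease Resistance,0,0,0,0.00
Best,Isinya,Dorper,Breed Attributes,0,0,1,0.02
Best,Amboseli,Cross,Body Size and Growth,12,2,4,0.30
Best,Amboseli,Cross,Condition,3,4,0,0.12
Best,Amboseli,Cross,Milk Production,3,6,3,0.20
Best,Amboseli,Cross,Reproduction and Mothering Ability,6,4,0,0.17
Best,Amboseli,Cross,Drought Tolerance,3,2,1,0.10
Best,Amboseli,Cross,Disease Resistance,0,0,0,0.00
Best,Amboseli,Cross,Breed Attributes,3,2,2,0.12
Best,Isinya,Cross,Body Size and Growth,21,4,3,0.58
Best,Isinya,Cross,Condition,0,0,0,0.00
Best,Isinya,Cross,Milk Production,0,8,2,0.21
Best,Isinya,Cross,Reproduction and Mothering Ability,0,4,2,0.13
Best,Isinya,Cross,Drought Tolerance,3,0,0,0.06
Best,Isinya,Cross,Disease Resistance,0,0,1,0.02
Best,Isinya,Cross,Breed Attributes,0,0,0,0.00
Poor,Amboseli,Red Maasai,Body Size and Growth,3,0,3,0.15
Poor,Amboseli,Red Maasai,Condition,9,2,2,0.33
Poor,Amboseli,Red Maasai,Milk Production,3,6,0,0.23
Poor,Amboseli,Red Maasai,Reproduction and Mothering Ability,0,6,1,0.18
Poor,Amboseli,Red Maasai,Drought Tolerance,0,0,0,0.00
Poor,Amboseli,Red Maasai,Disease Resistance,3,0,0,0.08
Poor,Amboseli,Red Maasai,Breed Attributes,0,2,0,0.05
Poor,Isinya,Red Maasai,Body Size and Growth,9,2,5,0.36
Poor,Isinya,Red Maasai,Condition,3,0,0,0.07
Poor,Isinya,Red Maasai,Milk Production,6,8,2,0.36
Poor,Isinya,Red Maasai,Reproduction and Mothering Ability,0,0,0,0.00
Poor,Isinya,Red Maasai,Drought Tolerance,0,2,0,0.04
Poor,Isinya,Red Maasai,Disease Resistance,6,0,0,0.13
Poor,Isinya,Red Maasai,Breed Attributes,0,2,0,0.04
Poor,Amboseli,Dorper,Body Size and Growth,3,0,0,0.09
Poor,Amboseli,Dorper,Condition,0,0,2,0.06
Poor,Amboseli,Dorper,Milk Production,0,6,2,0.25
Poor,Amboseli,Dorper,Reproduction and Mothering Ability,6,4,0,0.31
Poor,Amboseli,Dorper,Drought Tolerance,0,0,0,0.00
Poor,Amboseli,Dorper,Disease Resistance,9,0,0,0.28
Poor,Amboseli,Dorper,Breed Attributes,0,0,0,0.00
Poor,Isinya,Dorper,Body Size and Growth,0,0,2,0.07
Poor,Isinya,Dorper,Condition,0,0,0,0.00
Poor,Isinya,Dorper,Milk Production,6,6,2,0.52
Poor,Isinya,Dorper,Reproduction and Mothering Ability,3,2,0,0.19
Poor,Isinya,Dorper,Drought Tolerance,0,0,1,0.04
Poor,Isinya,Dorper,Disease Resistance,3,2,0,0.19
Poor,Isinya,Dorper,Breed Attributes,0,0,0,0.00
Poor,Amboseli,Cross,Body Size and Growth,3,0,2,0.12
Poor,Amboseli,Cross,Condition,0,6,1,0.17
Poor,Amboseli,Cross,Milk Production,3,4,4,0.27
Poor,Amboseli,Cross,Reproduction and Mothering Ability,3,2,2,0.17
Poor,Amboseli,Cross,Drought Tolerance,3,0,1,0.10
Poor,Amboseli,Cross,Disease Resistance,3,4,0,0.17
Poor,Amboseli,Cross,Breed Attributes,0,0,0,0.00
Poor,Isinya,Cross,Body Size and Growth,0,4,3,0.18
Poor,Isinya,Cross,Condition,0,0,0,0.00
Poor,Isinya,Cross,Milk Production,15,0,3,0.47
Poor,Isinya,Cross,Reproduction and Mothering Ability,0,2,2,0.11
Poor,Isinya,Cross,Drought Tolerance,0,2,0,0.05
Poor,Isinya,Cross,Disease Resistance,6,0,1,0.18
Poor,Isinya,Cross,Breed Attributes,0,0,0,0.00
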