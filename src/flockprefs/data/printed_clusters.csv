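quality,site,breed,cluster,wr_printed
Best,Amboseli,Red Maasai,Body Size and Growth,0.28
Best,Amboseli,Red Maasai,Condition,0.15
Best,Amboseli,Red Maasai,Reproduction and Milk,0.45
Best,Amboseli,Red Maasai,Adaptation,0.13
Best,Isinya,Red Maasai,Body Size and Growth,0.37
Best,Isinya,Red Maasai,Condition,0.00
Best,Isinya,Red Maasai,Reproduction and Milk,0.27
Best,Isinya,Red Maasai,Adaptation,0.37
Best,Amboseli,Dorper,Body Size and Growth,0.61
Best,Amboseli,Dorper,Condition,0.16
Best,Amboseli,Dorper,Reproduction and Milk,0.23
Best,Amboseli,Dorper,Adaptation,0.00
Best,Isinya,Dorper,Body Size and Growth,0.73
Best,Isinya,Dorper,Condition,0.00
Best,Isinya,Dorper,Reproduction and Milk,0.27
Best,Isinya,Dorper,Adaptation,0.00
Poor,Amboseli,Red Maasai,Body Size and Growth,0.16
Poor,Amboseli,Red Maasai,Condition,0.34
Poor,Amboseli,Red Maasai,Reproduction and Milk,0.42
Poor,Amboseli,Red Maasai,Adaptation,0.08
Poor,Isinya,Red Maasai,Body Size and Growth,0.37
Poor,Isinya,Red Maasai,Condition,0.07
Poor,Isinya,Red Maasai,Reproduction and Milk,0.37
Poor,Isinya,Red Maasai,Adaptation,0.19
Poor,Amboseli,Dorper,Body Size and Growth,0.09
Poor,Amboseli,Dorper,Condition,0.06
Poor,Amboseli,Dorper,Reproduction and Milk,0.56
Poor,Amboseli,Dorper,Adaptation,0.28
Poor,Isinya,Dorper,Body Size and Growth,0.07
Poor,Isinya,Dorper,Condition,0.00
Poor,Isinya,Dorper,Reproduction and Milk,0.70
Poor,Isinya,Dorper,Adaptation,0.22
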