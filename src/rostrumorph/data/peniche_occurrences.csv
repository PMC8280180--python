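subzone,P. bisulcata,C. longiforma,Bairstowius amaliae,P. milleri,Parapassaloteuthis sp.,Passaloteuthis sp. juv,Hastitidae indet,Acrocoelites sp.
Solare,13 (2|3|8),,10 (2|4|4),8 (3|5|0),,5 (0|0|5),,
Elisa,9 (1|7|1),23 (8|12|3),8 (1|6|1),3 (1|2|0),7 (3|0|4),2 (0|0|2),,
Mirabile,10 (1|5|4),17 (2|10|5),,,,,3 (indet.),
Semicelatum,3 (0|1|2),13 (3|6|4),,3 (1|0|2),4 (3|0|1),1 (0|0|1),,
Elegantulum,,,,,,,,2 (2|0|0)
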