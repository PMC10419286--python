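low,high,category
755,755,Nucleic Acids
764,764,Nucleic Acids
776,776,Nucleic Acids
779,779,Nucleic Acids
782,782,Nucleic Acids
788,788,Nucleic Acids
893,893,Nucleic Acids
982,982,Nucleic Acids
1085,1106,Nucleic Acids
1175,1196,Nucleic Acids
1304,1334,Nucleic Acids
1517,1589,Nucleic Acids
620,620,Proteins
764,764,Proteins
1004,1043,Proteins
1127,1127,Proteins
1229,1295,Proteins
1337,1349,Proteins
1409,1463,Proteins
1604,1676,Proteins
2942,2984,Proteins
1064,1064,Lipids
1130,1166,Lipids
1367,1376,Lipids
1463,1463,Lipids
1532,1538,Lipids
1742,1766,Lipids
2849,2849,Lipids
2873,2900,Lipids
3011,3011,Lipids
3023,3023,Lipids
2918,2918,Lipids and Proteins
2915,2915,Lipids and Proteins
527,527,Amino Acids
554,554,Amino Acids
596,596,Amino Acids
641,641,Amino Acids
647,647,Amino Acids
659,659,Amino Acids
695,695,Amino Acids
743,743,Amino Acids
815,839,Amino Acids
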