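# 4-acetamidophenol (paracetamol) Raman shift standard, ASTM E1840-96 values (cm-1)
# restricted to the working range of the instrument simulation (350-3100 cm-1)
position
390.9
465.1
504.0
651.6
710.8
797.2
834.5
857.9
968.7
1105.5
1168.5
1236.8
1278.5
1323.9
1371.5
1515.1
1561.6
1648.4
2931.1
3064.6
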