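14
toy butane, staggered anti geometry
C        0.00000000     0.00000000     0.00000000
C        1.53000000     0.00000000     0.00000000
C        2.10314809     1.41859130     0.00000000
C        3.63314809     1.41859130     0.00000000
H       -0.37280196     0.51213248    -0.88703947
H       -0.37280196    -1.02426496    -0.00000000
H       -0.37280196     0.51213248     0.88703947
H        1.86518689    -0.53750416     0.88703947
H        1.86518689    -0.53750416    -0.88703947
H        1.76796119     1.95609546     0.88703947
H        1.76796119     1.95609546    -0.88703947
H        4.00595004     0.90645882    -0.88703947
H        4.00595004     2.44285625     0.00000000
H        4.00595004     0.90645882     0.88703947
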