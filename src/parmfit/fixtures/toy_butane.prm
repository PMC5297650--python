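! parameter file written by parmfit

BONDS
CT     CT       222.500000     1.530000
CT     HC       309.000000     1.090000

ANGLES
CT     CT     CT        58.350000   112.000000    11.160000 2.5368549720184275
CT     CT     HC        33.430000   110.000000
HC     CT     HC        35.500000   108.800000

DIHEDRALS
X      CT     CT     X          0.160000   3   0.000000

IMPROPER

NONBONDED
CT     0.000000    -0.078000     2.040000
HC     0.000000    -0.024000     1.340000

END
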