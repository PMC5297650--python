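PSF

       1 !NTITLE
 REMARKS written by parmfit

      14 !NATOM
       1 LIG  1    LIG  C1   CT       -0.270000       12.0110           0
       2 LIG  1    LIG  C2   CT       -0.180000       12.0110           0
       3 LIG  1    LIG  C3   CT       -0.180000       12.0110           0
       4 LIG  1    LIG  C4   CT       -0.270000       12.0110           0
       5 LIG  1    LIG  H11  HC        0.090000        1.0080           0
       6 LIG  1    LIG  H12  HC        0.090000        1.0080           0
       7 LIG  1    LIG  H13  HC        0.090000        1.0080           0
       8 LIG  1    LIG  H21  HC        0.090000        1.0080           0
       9 LIG  1    LIG  H22  HC        0.090000        1.0080           0
      10 LIG  1    LIG  H31  HC        0.090000        1.0080           0
      11 LIG  1    LIG  H32  HC        0.090000        1.0080           0
      12 LIG  1    LIG  H41  HC        0.090000        1.0080           0
      13 LIG  1    LIG  H42  HC        0.090000        1.0080           0
      14 LIG  1    LIG  H43  HC        0.090000        1.0080           0

      13 !NBOND: bonds
       1       2       1       5       1       6       1       7
       2       3       2       8       2       9       3       4
       3      10       3      11       4      12       4      13
       4      14

      24 !NTHETA: angles
       1       2       3       1       2       8       1       2       9
       2       1       5       2       1       6       2       1       7
       2       3       4       2       3      10       2       3      11
       3       2       8       3       2       9       3       4      12
       3       4      13       3       4      14       4       3      10
       4       3      11       5       1       6       5       1       7
       6       1       7       8       2       9      10       3      11
      12       4      13      12       4      14      13       4      14

      27 !NPHI: dihedrals
       1       2       3       4       1       2       3      10
       1       2       3      11       2       3       4      12
       2       3       4      13       2       3       4      14
       5       1       2       3       5       1       2       8
       5       1       2       9       6       1       2       3
       6       1       2       8       6       1       2       9
       7       1       2       3       7       1       2       8
       7       1       2       9       8       2       3       4
       8       2       3      10       8       2       3      11
       9       2       3       4       9       2       3      10
       9       2       3      11      10       3       4      12
      10       3       4      13      10       3       4      14
      11       3       4      12      11       3       4      13
      11       3       4      14

       0 !NIMPHI: impropers

       0 !NDON

       0 !NACC

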