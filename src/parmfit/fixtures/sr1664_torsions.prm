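! Published torsion parameters for the PPARgamma non-agonist SR1664
! (torsions T1, T2, T3; atom names per the ligand numbering scheme)
! keys are atom names, standing in for atom types of the ligand topology

DIHEDRALS
C13  N2   C20  C21    0.1795  1    0.0   ! T1
C13  N2   C20  C21    0.3623  3    0.0   ! T1
C13  N2   C20  C21    0.4022  4    0.0   ! T1
N1   C9   C10  C11    0.1000  1  180.0   ! T2
N1   C9   C10  C11    0.7100  2  180.0   ! T2
C5   C7   N1   C9     1.5000  1  180.0   ! T3
C5   C7   N1   C9     0.1900  2    0.0   ! T3
C5   C7   N1   C9     0.2000  3    0.0   ! T3
C5   C7   N1   C9     0.7000  4    0.0   ! T3

END
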