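! Published torsion parameters for the PPARgamma partial agonist GQ16
! (torsions T1, T2, T3; atom names per the ligand numbering scheme)
! T1 keeps its negative force constant verbatim (signed-k convention,
! equivalent to +0.3572 with phase 0 up to an additive constant)

DIHEDRALS
C11  N1   C12  C13   -0.3572  4  180.0   ! T1
C6   C7   C8   C9     2.8584  1    0.0   ! T2
C6   C7   C8   C9     5.6498  2  180.0   ! T2
C6   C7   C8   C9     0.8824  3    0.0   ! T2
S1   C9   C8   C7     2.4869  1    0.0   ! T3
S1   C9   C8   C7    10.3926  2  180.0   ! T3
S1   C9   C8   C7     0.6072  3    0.0   ! T3
S1   C9   C8   C7     0.8350  4    0.0   ! T3

END
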