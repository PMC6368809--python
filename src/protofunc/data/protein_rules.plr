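# Protein specification rule base: premises encoding well-known protein
# characteristics.  Predicates: ST structure, FD folding, F function,
# AAS amino-acid sequence, CBND covalent protein-ligand bond,
# PPI protein-protein interaction, NCBND non-covalent protein-protein bond,
# PCF protein complex of functions.  Px, Py are protein variables, Ly a
# ligand variable.
R1: FD(Px) -> (ST(Px) -> F(Px))
R2: AAS(Px) -> ST(Px)
R3: AAS(Px) -> F(Px)
R4: CBND(Px, Ly) | AAS(Px) -> ST(Px)
R5: (FD(Px) | ST(Px)) -> F(Px)
R6: PPI(Px, Py) -> PCF(Px, Py)
R7: PCF(Px, Py) -> (F(Px) -> F(Py))
R8: PCF(Px, Py) -> F(Px) | F(Py)
R9: (ST(Px) & ST(Py)) -> (F(Px) -> F(Py))
R10: (AAS(Px) & AAS(Py)) -> (ST(Px) -> F(Py))
R11: CBND(Px, Ly) & F(Px) -> AAS(Px)
R12: NCBND(Px, Py) -> PPI(Px, Py)
R13: ST(Px) -> AAS(Px)
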