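# Ligand atom-type SMARTS rules.  Each rule lists a type label from the
# 29-label ligand vocabulary, a SMARTS pattern, and the indices of the matched
# atoms that receive the label (default [0]).  An atom may match several rules
# and then carries several labels.  Hydrogens are never typed.
#
# Vocabulary order (fixes the ligand axis of the interaction fingerprint):
#   Aromatic, Hetero, Halogen, Negative Ionizable, Positive Ionizable,
#   H-bond Donor, H-bond Acceptor, Amide Nitrogen, Amine Nitrogen, Vinyl,
#   Carboxylate Oxygen, Alcohol Oxygen, Nitro Oxygen, Nitro Nitrogen,
#   Phosphate Oxygen, Sulfone Sulfur, Sulfoxide Sulfur, Enol Oxygen,
#   Imine Nitrogen, Enamine Nitrogen, Aromatic Nitrogen, Aromatic Oxygen,
#   Aromatic Sulfur, Aromatic Carbon, Aliphatic Carbon, F, Cl, Br, I

rules:
  - {type: Aromatic, smarts: "[a]"}
  - {type: Hetero, smarts: "[#7,#8,#16,#15]"}
  - {type: Halogen, smarts: "[F,Cl,Br,I]"}
  - {type: Negative Ionizable, smarts: "[CX3](=[OX1])[OX2H1,OX1-]", atoms: [1, 2]}
  - {type: Negative Ionizable, smarts: "[SX4](=[OX1])(=[OX1])[OX2H1,OX1-]", atoms: [1, 2, 3]}
  - {type: Negative Ionizable, smarts: "[O-;!$([O-]~[N+])]"}
  - {type: Positive Ionizable, smarts: "[NX4+,NX3+;!$([N+][O-])]"}
  - {type: Positive Ionizable, smarts: "[NX3;H2,H1;!$([NX3][CX3]=[OX1,NX2,SX1]);!$([NX3]a);!$([NX3][#7,#8])]"}
  - {type: Positive Ionizable, smarts: "[NX3][CX3](=[NX2])[NX3]", atoms: [0, 2, 3]}
  - {type: H-bond Donor, smarts: "[NX3;!H0]"}
  - {type: H-bond Donor, smarts: "[OX2;!H0]"}
  - {type: H-bond Donor, smarts: "[SX2;!H0]"}
  - {type: H-bond Donor, smarts: "[nX3;!H0]"}
  - {type: H-bond Acceptor, smarts: "[OX1;!$([OX1]~[N+])]"}
  - {type: H-bond Acceptor, smarts: "[OX2;!$([OX2]a)]"}
  - {type: H-bond Acceptor, smarts: "[NX2;!$([NX2]=[OX1])]"}
  - {type: H-bond Acceptor, smarts: "[nX2]"}
  - {type: H-bond Acceptor, smarts: "[NX3;!$([NX3][CX3]=[OX1]);!$([NX3]a);!$([NX3]~[OX1])]"}
  - {type: Amide Nitrogen, smarts: "[NX3][CX3]=[OX1]"}
  - {type: Amine Nitrogen, smarts: "[NX3;!a;!$([NX3][CX3]=[OX1]);!$([NX3][CX3]=[CX3]);!$([NX3]~[OX1]);!$([NX3][NX2])]"}
  - {type: Vinyl, smarts: "[CX3;!a]=[CX3;!a]", atoms: [0, 1]}
  - {type: Carboxylate Oxygen, smarts: "[CX3](=[OX1])[OX2H1,OX1-]", atoms: [1, 2]}
  - {type: Alcohol Oxygen, smarts: "[OX2H][CX4]"}
  - {type: Nitro Oxygen, smarts: "[OX1]~[#7X3]~[OX1]", atoms: [0, 2]}
  - {type: Nitro Nitrogen, smarts: "[#7X3](~[OX1])~[OX1]"}
  - {type: Phosphate Oxygen, smarts: "[#8]~[#15]"}
  - {type: Sulfone Sulfur, smarts: "[SX4](=[OX1])=[OX1]"}
  - {type: Sulfoxide Sulfur, smarts: "[SX3]=[OX1]"}
  - {type: Enol Oxygen, smarts: "[OX2H][CX3]=[CX3]"}
  - {type: Imine Nitrogen, smarts: "[NX2;!a]=[CX3;!a]"}
  - {type: Enamine Nitrogen, smarts: "[NX3][CX3]=[CX3]"}
  - {type: Aromatic Nitrogen, smarts: "[n]"}
  - {type: Aromatic Oxygen, smarts: "[o]"}
  - {type: Aromatic Sulfur, smarts: "[s]"}
  - {type: Aromatic Carbon, smarts: "[c]"}
  - {type: Aliphatic Carbon, smarts: "[C]"}
  - {type: F, smarts: "[F]"}
  - {type: Cl, smarts: "[Cl]"}
  - {type: Br, smarts: "[Br]"}
  - {type: I, smarts: "[I]"}
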