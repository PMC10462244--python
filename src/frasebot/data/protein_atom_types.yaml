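# Protein atom-type templates: (residue name, atom name) -> list of labels from
# the 13-label protein vocabulary.  Atoms not listed here fall back to the
# element defaults below.  Hydrogens are never typed.
#
# Vocabulary (order fixes the protein axis of the interaction fingerprint):
#   Aromatic, NegativeIonizable, Positive Ionizable, H-bond Donor,
#   H-bond Acceptor, Amide Nitrogen, Amine Nitrogen, Carboxylate Oxygen,
#   Alcohol Oxygen, Imine Nitrogen, Aromatic Nitrogen, Aromatic Carbon,
#   Aliphatic Carbon

element_defaults:
  C: [Aliphatic Carbon]
  N: [H-bond Donor]
  O: [H-bond Acceptor]
  S: []

backbone:
  N: [H-bond Donor, Amide Nitrogen]
  O: [H-bond Acceptor]
  OXT: [H-bond Acceptor, NegativeIonizable, Carboxylate Oxygen]
  C: [Aliphatic Carbon]
  CA: [Aliphatic Carbon]

side_chains:
  ARG:
    NE: [Positive Ionizable, H-bond Donor, Amine Nitrogen]
    NH1: [Positive Ionizable, H-bond Donor, Amine Nitrogen]
    NH2: [Positive Ionizable, H-bond Donor, Amine Nitrogen]
  LYS:
    NZ: [Positive Ionizable, H-bond Donor, Amine Nitrogen]
  ASP:
    OD1: [NegativeIonizable, H-bond Acceptor, Carboxylate Oxygen]
    OD2: [NegativeIonizable, H-bond Acceptor, Carboxylate Oxygen]
  GLU:
    OE1: [NegativeIonizable, H-bond Acceptor, Carboxylate Oxygen]
    OE2: [NegativeIonizable, H-bond Acceptor, Carboxylate Oxygen]
  ASN:
    OD1: [H-bond Acceptor]
    ND2: [H-bond Donor, Amide Nitrogen]
  GLN:
    OE1: [H-bond Acceptor]
    NE2: [H-bond Donor, Amide Nitrogen]
  SER:
    OG: [H-bond Donor, H-bond Acceptor, Alcohol Oxygen]
  THR:
    OG1: [H-bond Donor, H-bond Acceptor, Alcohol Oxygen]
  TYR:
    OH: [H-bond Donor, H-bond Acceptor, Alcohol Oxygen]
    CG: [Aromatic, Aromatic Carbon]
    CD1: [Aromatic, Aromatic Carbon]
    CD2: [Aromatic, Aromatic Carbon]
    CE1: [Aromatic, Aromatic Carbon]
    CE2: [Aromatic, Aromatic Carbon]
    CZ: [Aromatic, Aromatic Carbon]
  PHE:
    CG: [Aromatic, Aromatic Carbon]
    CD1: [Aromatic, Aromatic Carbon]
    CD2: [Aromatic, Aromatic Carbon]
    CE1: [Aromatic, Aromatic Carbon]
    CE2: [Aromatic, Aromatic Carbon]
    CZ: [Aromatic, Aromatic Carbon]
  TRP:
    CG: [Aromatic, Aromatic Carbon]
    CD1: [Aromatic, Aromatic Carbon]
    CD2: [Aromatic, Aromatic Carbon]
    NE1: [H-bond Donor, Aromatic, Aromatic Nitrogen]
    CE2: [Aromatic, Aromatic Carbon]
    CE3: [Aromatic, Aromatic Carbon]
    CZ2: [Aromatic, Aromatic Carbon]
    CZ3: [Aromatic, Aromatic Carbon]
    CH2: [Aromatic, Aromatic Carbon]
  HIS:
    CG: [Aromatic, Aromatic Carbon]
    CD2: [Aromatic, Aromatic Carbon]
    CE1: [Aromatic, Aromatic Carbon]
    ND1: [H-bond Acceptor, Aromatic, Aromatic Nitrogen]
    NE2: [H-bond Donor, Aromatic, Aromatic Nitrogen]
  CYS:
    SG: []
  MET:
    SD: []
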