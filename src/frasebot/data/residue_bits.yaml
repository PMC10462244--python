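# Per-residue 11-bit many-hot encodings.
#
# Layout (0-based positions):
#   0-2  size           3-bit thermometer over side-chain heavy-atom count
#                       (0-1 -> 000, 2-3 -> 100, 4-5 -> 110, >=6 -> 111)
#   3-5  hydrophobicity 3-bit thermometer over the Fauchere-Pliska side-chain
#                       pi scale (pi<=0 -> 000, 0<pi<=0.6 -> 100,
#                       0.6<pi<=1.5 -> 110, pi>1.5 -> 111)
#   6    H-bond acceptor (side chain)
#   7    H-bond donor (side chain)
#   8    positive ionizable
#   9    negative ionizable
#   10   aromatic
#
# Histidine is encoded as a neutral aromatic donor/acceptor (dominant state at
# pH 7.4); swap in an alternative table via the `table` argument to
# encode_residue to change that.
ALA: [0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0]
ARG: [1, 1, 1, 0, 0, 0, 0, 1, 1, 0, 0]
ASN: [1, 1, 0, 0, 0, 0, 1, 1, 0, 0, 0]
ASP: [1, 1, 0, 0, 0, 0, 1, 0, 0, 1, 0]
CYS: [1, 0, 0, 1, 1, 1, 0, 0, 0, 0, 0]
GLN: [1, 1, 0, 0, 0, 0, 1, 1, 0, 0, 0]
GLU: [1, 1, 0, 0, 0, 0, 1, 0, 0, 1, 0]
GLY: [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
HIS: [1, 1, 1, 1, 0, 0, 1, 1, 0, 0, 1]
ILE: [1, 1, 0, 1, 1, 1, 0, 0, 0, 0, 0]
LEU: [1, 1, 0, 1, 1, 1, 0, 0, 0, 0, 0]
LYS: [1, 1, 0, 0, 0, 0, 0, 1, 1, 0, 0]
MET: [1, 1, 0, 1, 1, 0, 0, 0, 0, 0, 0]
PHE: [1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 1]
PRO: [1, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0]
SER: [1, 0, 0, 0, 0, 0, 1, 1, 0, 0, 0]
THR: [1, 0, 0, 1, 0, 0, 1, 1, 0, 0, 0]
TRP: [1, 1, 1, 1, 1, 1, 0, 1, 0, 0, 1]
TYR: [1, 1, 1, 1, 1, 0, 1, 1, 0, 0, 1]
VAL: [1, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0]
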