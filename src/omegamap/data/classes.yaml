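# Lipid class and adduct registry.
#
# classes: maps a class name to
#   backbone - elemental formula of the glycerophospho-headgroup core, i.e.
#              the molecule obtained by removing all chain residues; each
#              ester chain c:d then adds C(c) H(2c-2-2d) O, an O- (alkyl
#              ether) chain adds C(c) H(2c-2d), and a P- (alkenyl / vinyl
#              ether) chain adds C(c) H(2c-2-2d)
#   chains   - number of chain positions (1 for lyso classes, 2 otherwise)
#   adducts  - default adducts for mass-list generation
#
# adducts: composition delta (may be negative) and charge; m/z is
#   (M + delta - charge * m_e) / |charge|.
adducts:
  "[M+H]+":    {composition: {H: 1},           charge: 1}
  "[M+Na]+":   {composition: {Na: 1},          charge: 1}
  "[M+NH4]+":  {composition: {N: 1, H: 4},     charge: 1}
  "[M-H]-":    {composition: {H: -1},          charge: -1}
  "[M+HCOO]-": {composition: {C: 1, H: 1, O: 2}, charge: -1}

classes:
  PC:      {backbone: C8H20NO6P,  chains: 2, adducts: ["[M+H]+", "[M+Na]+"]}
  "PC O-": {backbone: C8H20NO6P,  chains: 2, adducts: ["[M+H]+", "[M+Na]+"]}
  "PC P-": {backbone: C8H20NO6P,  chains: 2, adducts: ["[M+H]+", "[M+Na]+"]}
  LPC:     {backbone: C8H20NO6P,  chains: 1, adducts: ["[M+H]+", "[M+Na]+"]}
  PE:      {backbone: C5H14NO6P,  chains: 2, adducts: ["[M+H]+", "[M-H]-"]}
  "PE P-": {backbone: C5H14NO6P,  chains: 2, adducts: ["[M+H]+", "[M-H]-"]}
  LPE:     {backbone: C5H14NO6P,  chains: 1, adducts: ["[M+H]+", "[M-H]-"]}
  PI:      {backbone: C9H19O11P,  chains: 2, adducts: ["[M+NH4]+", "[M-H]-"]}
  LPI:     {backbone: C9H19O11P,  chains: 1, adducts: ["[M+NH4]+", "[M-H]-"]}
  PG:      {backbone: C6H15O8P,   chains: 2, adducts: ["[M+NH4]+", "[M-H]-"]}
  LPG:     {backbone: C6H15O8P,   chains: 1, adducts: ["[M+NH4]+", "[M-H]-"]}
  BMP:     {backbone: C6H15O8P,   chains: 2, adducts: ["[M+NH4]+", "[M-H]-"]}
  PS:      {backbone: C6H14NO8P,  chains: 2, adducts: ["[M+H]+", "[M-H]-"]}
  LPS:     {backbone: C6H14NO8P,  chains: 1, adducts: ["[M+H]+", "[M-H]-"]}
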