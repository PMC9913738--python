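# Lipid class registry: sum-composition grammar and acquisition routing.
#
# backbone        elemental composition of a virtual species with C=0, DB=0 (and OH=0 for
#                 sphingolipids); the full species composition is backbone + C x CH2
#                 - DB x H2 + OH x O.  Backbones are fixed so that the assembled formulas
#                 reproduce the standard sum-composition formulas (e.g. PC(34:2) ->
#                 C42H80NO8P, SM(34:1:2) -> C39H79N2O6P).
# chains          number of fatty chains contributing to the C/DB indices (bookkeeping).
# sphingoid       true -> three-index labels "(C:DB:OH)"; the OH index adds O atoms.
# quant_polarity  the single polarity in which the class is quantified.
# quant_adduct    the adduct used for quantification in that polarity.
# extra_adducts   additional detectable adducts, mapped to their polarity.
# c_range/c_step/db_range/oh_values
#                 the realistic species grid for candidate generation and simulation;
#                 grids additionally obey DB <= C // 3.
# membrane        counts toward the membrane-lipid denominator (glycerophospho- and
#                 sphingolipids); storage lipids DG/TG/CE do not.
#
# Isomeric pairs are merged: PC-O(x:y) also stands for PC-P(x:y-1) (same for PE-P /
# PE-O(x:y+1)), and PG/BMP is one collective class.

classes:
  PC:
    backbone: C8H16NO8P
    chains: 2
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M+Cl]-"
    extra_adducts: {"[M+H]+": "+", "[M+Na]+": "+"}
    c_range: [30, 40]
    c_step: 2
    db_range: [0, 6]
    membrane: true
  PC-O:
    backbone: C8H18NO7P
    chains: 2
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M+Cl]-"
    extra_adducts: {"[M+H]+": "+", "[M+Na]+": "+"}
    c_range: [32, 38]
    c_step: 2
    db_range: [0, 4]
    membrane: true
  PE:
    backbone: C5H10NO8P
    chains: 2
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [32, 40]
    c_step: 2
    db_range: [0, 6]
    membrane: true
  PE-P:
    backbone: C5H10NO7P
    chains: 2
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [34, 40]
    c_step: 2
    db_range: [0, 6]
    membrane: true
  PI:
    backbone: C9H15O13P
    chains: 2
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [32, 40]
    c_step: 2
    db_range: [0, 6]
    membrane: true
  PS:
    backbone: C6H10NO10P
    chains: 2
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [34, 40]
    c_step: 2
    db_range: [0, 6]
    membrane: true
  PA:
    backbone: C3H5O8P
    chains: 2
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [28, 40]
    c_step: 2
    db_range: [0, 6]
    membrane: true
  PG/BMP:
    backbone: C6H11O10P
    chains: 2
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [32, 44]
    c_step: 2
    db_range: [0, 12]
    membrane: true
  CL:
    backbone: C9H14O17P2
    chains: 4
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M-2H]2-"
    extra_adducts: {}
    c_range: [64, 80]
    c_step: 2
    db_range: [2, 10]
    db_step: 2
    membrane: true
  LPC:
    backbone: C8H18NO7P
    chains: 1
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M+Cl]-"
    extra_adducts: {}
    c_range: [14, 20]
    c_step: 1
    db_range: [0, 3]
    membrane: true
  LPE:
    backbone: C5H12NO7P
    chains: 1
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [14, 20]
    c_step: 1
    db_range: [0, 3]
    membrane: true
  LPI:
    backbone: C9H17O12P
    chains: 1
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [14, 20]
    c_step: 1
    db_range: [0, 3]
    membrane: true
  LPS:
    backbone: C6H12NO9P
    chains: 1
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [14, 20]
    c_step: 1
    db_range: [0, 3]
    membrane: true
  LPG:
    backbone: C6H13O9P
    chains: 1
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [14, 20]
    c_step: 1
    db_range: [0, 3]
    membrane: true
  LCL:
    # even-DB grid, mirroring the even-DB cardiolipin pool it derives from
    backbone: C9H16O16P2
    chains: 3
    sphingoid: false
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [48, 60]
    c_step: 2
    db_range: [0, 6]
    db_step: 2
    membrane: true
  Cer:
    backbone: HNO
    chains: 2
    sphingoid: true
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [32, 44]
    c_step: 2
    db_range: [1, 2]
    oh_values: [2]
    membrane: true
  HexCer:
    backbone: C6H11NO6
    chains: 2
    sphingoid: true
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [32, 44]
    c_step: 2
    db_range: [1, 2]
    oh_values: [2]
    membrane: true
  GM3:
    # d18:1 long-chain base with predominantly saturated fatty acids -> (x:1) species
    backbone: C23H38N2O19
    chains: 2
    sphingoid: true
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [32, 42]
    c_step: 2
    db_range: [1, 1]
    oh_values: [2]
    membrane: true
  Sulf:
    backbone: C6H11NO9S
    chains: 2
    sphingoid: true
    quant_polarity: "-"
    quant_adduct: "[M-H]-"
    extra_adducts: {}
    c_range: [32, 44]
    c_step: 2
    db_range: [1, 2]
    oh_values: [2]
    membrane: true
  SM:
    backbone: C5H13N2O4P
    chains: 2
    sphingoid: true
    quant_polarity: "+"
    quant_adduct: "[M+H]+"
    extra_adducts: {}
    c_range: [32, 42]
    c_step: 2
    db_range: [1, 2]
    oh_values: [2]
    membrane: true
  DG:
    backbone: C3H4O5
    chains: 2
    sphingoid: false
    quant_polarity: "+"
    quant_adduct: "[M+NH4]+"
    extra_adducts: {}
    c_range: [32, 36]
    c_step: 2
    db_range: [0, 4]
    membrane: false
  TG:
    backbone: C3H2O6
    chains: 3
    sphingoid: false
    quant_polarity: "+"
    quant_adduct: "[M+NH4]+"
    extra_adducts: {}
    c_range: [48, 56]
    c_step: 2
    db_range: [0, 6]
    membrane: false
  CE:
    backbone: C27H44O2
    chains: 1
    sphingoid: false
    quant_polarity: "+"
    quant_adduct: "[M+NH4]+"
    extra_adducts: {}
    c_range: [16, 22]
    c_step: 2
    db_range: [0, 6]
    membrane: false
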