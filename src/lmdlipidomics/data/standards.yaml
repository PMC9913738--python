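# Default internal-standard set: one non-endogenous species per quantified class with its
# spiked amount in pmol per sample.  Odd-carbon (or otherwise off-grid) species are chosen
# so that no standard coincides with an endogenous grid species.  Amounts are editable
# defaults of this package's simulated acquisition, not measured values.
standards:
  PC:     {species: "PC(25:0)",      pmol: 10.0}
  PC-O:   {species: "PC-O(25:0)",    pmol: 4.0}
  PE:     {species: "PE(25:0)",      pmol: 8.0}
  PE-P:   {species: "PE-P(25:0)",    pmol: 4.0}
  PI:     {species: "PI(25:0)",      pmol: 4.0}
  PS:     {species: "PS(25:0)",      pmol: 4.0}
  PA:     {species: "PA(25:0)",      pmol: 2.0}
  PG/BMP: {species: "PG/BMP(25:0)",  pmol: 2.0}
  CL:     {species: "CL(56:0)",      pmol: 4.0}
  LPC:    {species: "LPC(13:0)",     pmol: 1.0}
  LPE:    {species: "LPE(13:0)",     pmol: 1.0}
  LPI:    {species: "LPI(13:0)",     pmol: 1.0}
  LPS:    {species: "LPS(13:0)",     pmol: 1.0}
  LPG:    {species: "LPG(13:0)",     pmol: 1.0}
  LCL:    {species: "LCL(42:0)",     pmol: 1.0}
  Cer:    {species: "Cer(30:1:2)",   pmol: 2.0}
  HexCer: {species: "HexCer(30:1:2)", pmol: 2.0}
  GM3:    {species: "GM3(30:1:2)",   pmol: 2.0}
  Sulf:   {species: "Sulf(30:1:2)",  pmol: 2.0}
  SM:     {species: "SM(30:1:2)",    pmol: 5.0}
  DG:     {species: "DG(24:0)",      pmol: 5.0}
  TG:     {species: "TG(39:0)",      pmol: 10.0}
  CE:     {species: "CE(13:0)",      pmol: 5.0}
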