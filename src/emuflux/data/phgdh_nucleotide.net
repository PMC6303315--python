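# Reconstructed serine-synthesis / pentose-phosphate / TCA / nucleotide
# network: 19 reactions, 21 metabolites.  Glucose enters as G6P and the
# uniformly 13C-labeled tracer is applied there.  Succinate/fumarate
# scrambling is written as two half-weight mapping variants of TCA2.
# Surplus one-carbon units (methylene-THF not consumed by purine synthesis
# or biomass) leave as formate.  Biomass drain coefficients are per unit
# growth rate, from typical dry-cell-weight composition (protein amino
# acids >> nucleotide monomers).
SOURCE G6P 6
SOURCE SER_E 3
SOURCE GLY_E 2
SOURCE ASP_E 4
SOURCE INO_E 10
SOURCE URD_E 9
SOURCE CO2 1
SINK FOR
BIOMASS SER 0.30
BIOMASS GLY 0.45
BIOMASS MEETHF 0.05
BIOMASS ASP 0.35
BIOMASS IMP 0.06
BIOMASS UMP 0.05
# --- pentose phosphate pathway (lumped oxidative branch) ---
PPP: 1 G6P (abcdef) -> 1 R5P (bcdef) + 1 CO2 (a)
# --- glycolysis G6P -> 2x 3PG (triose mirror on the DHAP half) ---
EMP: 1 G6P (abcdef) -> 1 3PG (cba) + 1 3PG (def)
PK: 1 3PG (abc) -> 1 PYR (abc)
# --- serine synthesis pathway and one-carbon metabolism ---
SSP: 1 3PG (abc) -> 1 SER (abc)
SHMT: 1 SER (abc) -> 1 GLY (ab) + 1 MEETHF (c)
FOR_EX: 1 MEETHF (a) -> 1 FOR (a)
# --- TCA cycle (lumped; both released CO2 derive from OAA carbons) ---
PDH: 1 PYR (abc) -> 1 ACCOA (bc) + 1 CO2 (a)
PC: 1 PYR (abc) + 1 CO2 (d) -> 1 OAA (abcd)
CS: 1 ACCOA (ab) + 1 OAA (cdef) -> 1 AKG (defba) + 1 CO2 (c)
TCA2: 1 AKG (abcde) -> 1 OAA (bcde) + 1 CO2 (a)
TCA2: 1 AKG (abcde) -> 1 OAA (edcb) + 1 CO2 (a)
ASPS: 1 OAA (abcd) -> 1 ASP (abcd)
# --- exogenous uptake ---
SER_UPT: 1 SER_E (abc) -> 1 SER (abc)
GLY_UPT: 1 GLY_E (ab) -> 1 GLY (ab)
ASP_UPT: 1 ASP_E (abcd) -> 1 ASP (abcd)
# --- nucleotide synthesis and salvage ---
CAPS: 1 CO2 (a) -> 1 CAP (a)
IMP_DN: 1 R5P (abcde) + 1 GLY (fg) + 1 MEETHF (h) + 1 MEETHF (i) + 1 CO2 (j) -> 1 IMP (abcdefghij)
IMP_SALV: 1 INO_E (abcdefghij) -> 1 IMP (abcdefghij)
UMP_DN: 1 R5P (abcde) + 1 ASP (fghi) + 1 CAP (j) -> 1 UMP (abcdefghj) + 1 CO2 (i)
UMP_SALV: 1 URD_E (abcdefghi) -> 1 UMP (abcdefghi)
# --- branch registry: how each flux ratio is read off measured MIDs ---
BRANCH SER SSP = L(SER) / L(3PG) REST SER_UPT
BRANCH GLY SHMT = GLY:2 / SER:3 REST GLY_UPT
BRANCH ASP ASPS = L(ASP) / L(OAA) REST ASP_UPT
BRANCH IMP IMP_DN = L(IMP) / L(R5P*GLY*MEETHF*MEETHF) REST IMP_SALV
BRANCH OAA PC = invert OAA:3 REST TCA2
BRANCH UMP UMP_DN = invert L(UMP) REST UMP_SALV
# --- display names of the reported fluxes ---
LABEL SSP 3PG->Ser
LABEL SHMT Ser->Gly
LABEL PPP G6P->R5P
LABEL PDH Pyr->AcCoA
LABEL PC Pyr->OAA
LABEL SER_UPT Ser uptake
LABEL GLY_UPT Gly uptake
LABEL ASP_UPT Asp uptake
LABEL IMP_DN IMP synthesis
LABEL IMP_SALV IMP salvage
LABEL UMP_DN UMP synthesis
LABEL UMP_SALV UMP salvage
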