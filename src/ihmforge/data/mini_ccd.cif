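data_mini_ccd
#
# Bundled subset of the Chemical Component Dictionary: the 20 standard
# amino acids, water and a handful of common ligands.  A full CCD file in
# the same layout can be supplied instead.
#
loop_
_chem_comp.id
_chem_comp.name
_chem_comp.formula
_chem_comp.type
ALA ALANINE 'C3 H7 N O2' 'L-peptide linking'
ARG ARGININE 'C6 H15 N4 O2' 'L-peptide linking'
ASN ASPARAGINE 'C4 H8 N2 O3' 'L-peptide linking'
ASP 'ASPARTIC ACID' 'C4 H7 N O4' 'L-peptide linking'
CYS CYSTEINE 'C3 H7 N O2 S' 'L-peptide linking'
GLN GLUTAMINE 'C5 H10 N2 O3' 'L-peptide linking'
GLU 'GLUTAMIC ACID' 'C5 H9 N O4' 'L-peptide linking'
GLY GLYCINE 'C2 H5 N O2' 'peptide linking'
HIS HISTIDINE 'C6 H10 N3 O2' 'L-peptide linking'
ILE ISOLEUCINE 'C6 H13 N O2' 'L-peptide linking'
LEU LEUCINE 'C6 H13 N O2' 'L-peptide linking'
LYS LYSINE 'C6 H15 N2 O2' 'L-peptide linking'
MET METHIONINE 'C5 H11 N O2 S' 'L-peptide linking'
PHE PHENYLALANINE 'C9 H11 N O2' 'L-peptide linking'
PRO PROLINE 'C5 H9 N O2' 'L-peptide linking'
SER SERINE 'C3 H7 N O3' 'L-peptide linking'
THR THREONINE 'C4 H9 N O3' 'L-peptide linking'
TRP TRYPTOPHAN 'C11 H12 N2 O2' 'L-peptide linking'
TYR TYROSINE 'C9 H11 N O3' 'L-peptide linking'
VAL VALINE 'C5 H11 N O2' 'L-peptide linking'
HOH WATER 'H2 O' non-polymer
ATP "ADENOSINE-5'-TRIPHOSPHATE" 'C10 H16 N5 O13 P3' non-polymer
ADP "ADENOSINE-5'-DIPHOSPHATE" 'C10 H15 N5 O10 P2' non-polymer
GTP "GUANOSINE-5'-TRIPHOSPHATE" 'C10 H16 N5 O14 P3' non-polymer
GDP "GUANOSINE-5'-DIPHOSPHATE" 'C10 H15 N5 O11 P2' non-polymer
HEM 'PROTOPORPHYRIN IX CONTAINING FE' 'C34 H32 Fe N4 O4' non-polymer
ZN 'ZINC ION' Zn non-polymer
MG 'MAGNESIUM ION' Mg non-polymer
CA 'CALCIUM ION' Ca non-polymer
NAD 'NICOTINAMIDE-ADENINE-DINUCLEOTIDE' 'C21 H27 N7 O14 P2' non-polymer
#
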