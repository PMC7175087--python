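# Internal-mismatch nearest-neighbor parameters for DNA duplex stacks.
# Stacks keyed XY/WZ: top strand 5'->3', bottom strand 3'->5'; exactly one
# position per key carries a non-Watson-Crick pairing.  Stacks with two
# mismatched pairings (sequential mismatches) are deliberately absent: the
# model treats them as undefined.
# dH in kcal/mol, dS in cal/(mol*K).
# Source: Allawi & SantaLucia (1997-1998) single internal mismatches in DNA
# (the Biopython MeltingTemp DNA_IMM1 set, inosine entries omitted).  Used
# here as the single-mismatch approximation for DNA:RNA hybrid stacks.
stack	dh	ds	source
AA/TA	1.2	1.7	allawi_santalucia_imm
AA/TC	2.3	4.6	allawi_santalucia_imm
AA/TG	-0.6	-2.3	allawi_santalucia_imm
AC/TA	5.3	14.6	allawi_santalucia_imm
AC/TC	0.0	-4.4	allawi_santalucia_imm
AC/TT	0.7	0.2	allawi_santalucia_imm
AG/TA	-0.7	-2.3	allawi_santalucia_imm
AG/TG	-3.1	-9.5	allawi_santalucia_imm
AG/TT	1.0	0.9	allawi_santalucia_imm
AT/TC	-1.2	-6.2	allawi_santalucia_imm
AT/TG	-2.5	-8.3	allawi_santalucia_imm
AT/TT	-2.7	-10.8	allawi_santalucia_imm
CA/GA	-0.9	-4.2	allawi_santalucia_imm
CA/GC	1.9	3.7	allawi_santalucia_imm
CA/GG	-0.7	-2.3	allawi_santalucia_imm
CC/GA	0.6	-0.6	allawi_santalucia_imm
CC/GC	-1.5	-7.2	allawi_santalucia_imm
CC/GT	-0.8	-4.5	allawi_santalucia_imm
CG/GA	-4.0	-13.2	allawi_santalucia_imm
CG/GG	-4.9	-15.3	allawi_santalucia_imm
CG/GT	-4.1	-11.7	allawi_santalucia_imm
CT/GC	-1.5	-6.1	allawi_santalucia_imm
CT/GG	-2.8	-8.0	allawi_santalucia_imm
CT/GT	-5.0	-15.8	allawi_santalucia_imm
GA/CA	-2.9	-9.8	allawi_santalucia_imm
GA/CC	5.2	14.2	allawi_santalucia_imm
GA/CG	-0.6	-1.0	allawi_santalucia_imm
GC/CA	-0.7	-3.8	allawi_santalucia_imm
GC/CC	3.6	8.9	allawi_santalucia_imm
GC/CT	2.3	5.4	allawi_santalucia_imm
GG/CA	0.5	3.2	allawi_santalucia_imm
GG/CG	-6.0	-15.8	allawi_santalucia_imm
GG/CT	3.3	10.4	allawi_santalucia_imm
GT/CC	5.2	13.5	allawi_santalucia_imm
GT/CG	-4.4	-12.3	allawi_santalucia_imm
GT/CT	-2.2	-8.4	allawi_santalucia_imm
TA/AA	4.7	12.9	allawi_santalucia_imm
TA/AC	3.4	8.0	allawi_santalucia_imm
TA/AG	0.7	0.7	allawi_santalucia_imm
TC/AA	7.6	20.2	allawi_santalucia_imm
TC/AC	6.1	16.4	allawi_santalucia_imm
TC/AT	1.2	0.7	allawi_santalucia_imm
TG/AA	3.0	7.4	allawi_santalucia_imm
TG/AG	1.6	3.6	allawi_santalucia_imm
TG/AT	-0.1	-1.7	allawi_santalucia_imm
TT/AC	1.0	0.7	allawi_santalucia_imm
TT/AG	-1.3	-5.3	allawi_santalucia_imm
TT/AT	0.2	-1.5	allawi_santalucia_imm
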