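# Nearest-neighbor thermodynamics for RNA:DNA heteroduplexes.
# Stacks keyed as rXY/dWZ with the RNA strand written 5'->3' in DNA letters
# (U printed as T) and the complementary DNA strand 3'->5' beneath it.
# dH in kcal/mol, dS in cal/(mol*K).
# Source: Sugimoto et al. (1995) Biochemistry 34:11211-11216 (the default
# RNA/DNA table of the Biopython MeltingTemp module, R_DNA_NN1).
stack	dh	ds	source
init	1.9	-3.9	sugimoto1995
AA/TT	-7.8	-21.9	sugimoto1995
AC/TG	-5.9	-12.3	sugimoto1995
AG/TC	-9.1	-23.5	sugimoto1995
AT/TA	-8.3	-23.9	sugimoto1995
CA/GT	-9.0	-26.1	sugimoto1995
CC/GG	-9.3	-23.2	sugimoto1995
CG/GC	-16.3	-47.1	sugimoto1995
CT/GA	-7.0	-19.7	sugimoto1995
GA/CT	-5.5	-13.5	sugimoto1995
GC/CG	-8.0	-17.1	sugimoto1995
GG/CC	-12.8	-31.9	sugimoto1995
GT/CA	-7.8	-21.6	sugimoto1995
TA/AT	-7.8	-23.2	sugimoto1995
TC/AG	-8.6	-22.9	sugimoto1995
TG/AC	-10.4	-28.4	sugimoto1995
TT/AA	-11.5	-36.4	sugimoto1995
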