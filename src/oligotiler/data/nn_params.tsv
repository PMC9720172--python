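# Unified nearest-neighbor thermodynamic parameters for DNA duplex
# formation in 1 M NaCl.
# Source: SantaLucia, J. (1998) "A unified view of polymer, dumbbell, and
# oligonucleotide DNA nearest-neighbor thermodynamics", PNAS 95:1460-1465
# (unified oligonucleotide parameter set, Table 1).
# dH in kcal/mol, dS in cal/(mol*K). Stacks are written 5'->3' on one
# strand; the table is strand-symmetric (stack == its reverse complement).
# INIT_AT / INIT_GC: duplex initiation, applied once per terminus
# according to the terminal base pair class. SYM: entropy penalty added
# once for self-complementary duplexes.
#
# Salt correction used by this package (monovalent only, applied to the
# entropy via the duplex phosphate count; n = duplex length in bp):
#   dS([Na+]) = dS(1 M) + 0.368 * (n - 1) * ln[Na+]
# with Tm(K) = 1000 * dH / (dS([Na+]) + R * ln(Ct / x)), R = 1.9872.
# version: 1
stack	dH_kcal_mol	dS_cal_molK
AA	-7.9	-22.2
AT	-7.2	-20.4
AC	-8.4	-22.4
AG	-7.8	-21.0
TA	-7.2	-21.3
TT	-7.9	-22.2
TC	-8.2	-22.2
TG	-8.5	-22.7
CA	-8.5	-22.7
CT	-7.8	-21.0
CC	-8.0	-19.9
CG	-10.6	-27.2
GA	-8.2	-22.2
GT	-8.4	-22.4
GC	-9.8	-24.4
GG	-8.0	-19.9
INIT_AT	2.3	4.1
INIT_GC	0.1	-2.8
SYM	0.0	-1.4
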