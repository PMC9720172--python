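"""Independent melting-temperature oracle for tests.

Retyped parameter table and a deliberately separate implementation of the
documented Tm model (stack summation, initiation by terminal class,
self-complement symmetry entropy, phosphate-count salt correction on dS,
strand-concentration term).  No code is shared with the package.
"""

import math

ORACLE_STACKS = {
    # stack: (dH kcal/mol, dS cal/mol/K) -- unified NN set, 1 M NaCl
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
ORACLE_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}
ORACLE_SYM_DS = -1.4
ORACLE_R = 1.9872

_COMP = str.maketrans("ACGT", "TGCA")


def oracle_revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_nn_sum(seq: str):
    dh = ORACLE_INIT[seq[0]][0] + ORACLE_INIT[seq[-1]][0]
    ds = ORACLE_INIT[seq[0]][1] + ORACLE_INIT[seq[-1]][1]
    pairs = [seq[i] + seq[i + 1] for i in range(len(seq) - 1)]
    dh += sum(ORACLE_STACKS[p][0] for p in pairs)
    ds += sum(ORACLE_STACKS[p][1] for p in pairs)
    if seq == oracle_revcomp(seq):
        ds += ORACLE_SYM_DS
    return dh, ds


def oracle_tm(seq: str, na: float = 0.05, ct: float = 1e-6) -> float:
    dh, ds = oracle_nn_sum(seq)
    x = 1 if seq == oracle_revcomp(seq) else 4
    ds_salt = ds + 0.368 * (len(seq) - 1) * math.log(na)
    return 1000.0 * dh / (ds_salt + ORACLE_R * math.log(ct / x)) - 273.15
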