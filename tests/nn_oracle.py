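"""Independent straight-line nearest-neighbor summation oracle.

Walks a duplex position by position over the published parameter
dictionaries; deliberately separate from the package's vectorized engine.
"""

import math

from Bio.SeqUtils import MeltingTemp as mt

R_GAS = 1.987


def brute_force_tm(sense: str, target: str,
                   probe_nM=25.0, target_nM=25.0, na_mM=50.0) -> float:
    """Straight-line NN summation over the published parameter dictionaries.

    Written independently of the package's vectorized engine: walks the
    duplex position by position, building each stack key from the target
    strand (DNA letters, 5'->3') over the probe strand (3'->5') and summing
    dH/dS from the hybrid stack table, falling back to the internal-mismatch
    table; returns NaN on any missing stack.
    """
    comp = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}
    top = target.replace("U", "T")
    bottom = "".join(comp[c] for c in sense)
    dh, ds = mt.R_DNA_NN1["init"]
    for i in range(len(top) - 1):
        mismatches = sum(sense[i + j] != target[i + j] for j in (0, 1))
        if mismatches == 2:
            return math.nan
        key = top[i:i + 2] + "/" + bottom[i:i + 2]
        tables = ((mt.R_DNA_NN1, key),) if mismatches == 0 else \
            ((mt.DNA_IMM1, key), (mt.DNA_IMM1, key[::-1]))
        for table, k in tables:
            if k in table and "I" not in k:
                dh += table[k][0]
                ds += table[k][1]
                break
        else:
            return math.nan
    ds += 0.368 * (len(top) - 1) * math.log(na_mM * 1e-3)
    k_eff = (probe_nM - target_nM / 2.0) * 1e-9
    return 1000.0 * dh / (ds + R_GAS * math.log(k_eff)) - 273.15

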