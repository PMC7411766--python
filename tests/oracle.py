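"""Independent brute-force mapping oracle for the test suite.

Scans every offset of every reference on both strands and counts
mismatches directly — no seeding, no index — so it shares no code path
with the package's mapper beyond base encoding.
"""

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from srna_census.sequences import encode, revcomp


def brute_force_map(read: str, refs: dict[str, str], max_mismatches: int):
    """All (ref_id, start, strand, mismatches) with mm <= max_mismatches.

    Sorted by (ref_id, start, strand); N never matches on either side.
    """
    out = []
    L = len(read)
    for rid in sorted(refs):
        enc_ref = encode(refs[rid])
        if len(enc_ref) < L or L == 0:
            continue
        windows = sliding_window_view(enc_ref, L)
        for strand, query in (("+", read), ("-", revcomp(read))):
            eq = encode(query)
            mm = ((windows != eq) | (windows == 4) | (eq == 4)).sum(axis=1)
            for start in np.flatnonzero(mm <= max_mismatches):
                out.append((rid, int(start), strand, int(mm[start])))
    out.sort(key=lambda t: (t[0], t[1], t[2]))
    return out


def mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Introduce exactly n_mut substitutions at distinct positions."""
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        out[p] = "ACGT"[("ACGT".index(out[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
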