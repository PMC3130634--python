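"""Shared independent oracles for the test suite."""

import numpy as np

from hydsel.seqcore import N_CODES, PointMutation, classify_mutation


def enumeration_expected_codes(seq, spectrum, scheme):
    """Brute-force P(code | one mutation) over all (position, alt) pairs."""
    probs = np.zeros(N_CODES)
    norm = spectrum.normalized_matrix
    L = len(seq.nt)
    for p in range(1, L + 1):
        ref = seq.nt[p - 1]
        for j, alt in enumerate("ACGT"):
            if alt == ref:
                continue
            w = norm["ACGT".index(ref), j] / L
            if w == 0:
                continue
            ch = classify_mutation(seq, PointMutation(p, ref, alt), scheme)
            probs[ch.code] += w
    return probs
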