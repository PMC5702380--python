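"""Independent brute-force oracles shared by unit and acceptance tests."""

import numpy as np


def grid_search_loglik(counts: np.ndarray, step: float = 0.001) -> float:
    """Exhaustive genotype log-likelihood maximum over the haplotype simplex.

    Enumerates every (f_AB, f_Ab, f_aB, f_ab) on the 3-simplex grid with
    the given step and evaluates the two-locus genotype likelihood
    directly — no EM, no gradient; the slow-but-sure check that EM finds
    the global maximum. Vectorised over the two inner coordinates.
    """
    k = int(round(1 / step))
    counts = np.asarray(counts, dtype=float)
    best = -np.inf
    cells = [(i, j, counts[i, j]) for i in range(3) for j in range(3) if counts[i, j] > 0]
    for i1 in range(k + 1):
        f1 = i1 * step
        rem = k - i1
        # all (f2, f3) with f2 + f3 <= rem*step; f4 is the remainder
        j2, j3 = np.meshgrid(np.arange(rem + 1), np.arange(rem + 1), indexing="ij")
        ok = (j2 + j3) <= rem
        f2 = j2[ok] * step
        f3 = j3[ok] * step
        f4 = np.maximum(1.0 - f1 - f2 - f3, 0.0)
        ll = np.zeros(f2.shape)
        with np.errstate(divide="ignore"):
            for gi, gj, c in cells:
                if (gi, gj) == (0, 0):
                    p = f1 * f1
                elif (gi, gj) == (0, 1):
                    p = 2 * f1 * f2
                elif (gi, gj) == (0, 2):
                    p = f2 * f2
                elif (gi, gj) == (1, 0):
                    p = 2 * f1 * f3
                elif (gi, gj) == (1, 1):
                    p = 2 * f1 * f4 + 2 * f2 * f3
                elif (gi, gj) == (1, 2):
                    p = 2 * f2 * f4
                elif (gi, gj) == (2, 0):
                    p = f3 * f3
                elif (gi, gj) == (2, 1):
                    p = 2 * f3 * f4
                else:
                    p = f4 * f4
                ll += c * np.log(p)
        m = np.nanmax(ll) if ll.size else -np.inf
        if m > best:
            best = m
    return float(best)
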