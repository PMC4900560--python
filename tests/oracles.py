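"""Independent brute-force / textbook-formula oracles used by the tests.

These deliberately take different computational routes from the package:
the F_ST oracles go through the ANOVA mean squares, EHH through explicit
pair enumeration, and pi through explicit pairwise Hamming distances.
"""

from itertools import combinations

import numpy as np


def wc_theta_ms(c1, n1, c2, n2):
    """Weir & Cockerham (1984) theta-hat via the ANOVA mean-squares route
    (haploid samples, r = 2 populations)."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    n1 = float(n1)
    n2 = float(n2)
    p1, p2 = c1 / n1, c2 / n2
    pbar = (c1 + c2) / (n1 + n2)
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2        # r - 1 = 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - 2)
    nc = n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)
    den = msp + (nc - 1) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den != 0, (msp - msg) / np.where(den == 0, 1, den), np.nan)


def reynolds_ratio_of_sums_ms(c1, n1, c2, n2):
    """Windowed Reynolds F_ST (ratio of per-site sums) via mean squares.

    Per site a = (MSP-MSG)/nc and a+b = (MSP+(nc-1)MSG)/nc; the window
    estimate is sum(a)/sum(a+b) over all sites given.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    n1 = float(n1)
    n2 = float(n2)
    p1, p2 = c1 / n1, c2 / n2
    pbar = (c1 + c2) / (n1 + n2)
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 + n2 - 2)
    nc = n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)
    a = (msp - msg) / nc
    ab = (msp + (nc - 1) * msg) / nc
    den = ab.sum()
    return np.nan if den == 0 else a.sum() / den


def ehh_brute(H, core, boundary):
    """EHH by exhaustive pair enumeration over the closed interval."""
    lo, hi = sorted((core, boundary))
    n = H.shape[0]
    num = sum(1 for i, j in combinations(range(n), 2)
              if np.array_equal(H[i, lo:hi + 1], H[j, lo:hi + 1]))
    return num / (n * (n - 1) / 2)


def pi_brute(H):
    """Mean pairwise difference count by exhaustive pair enumeration."""
    n = H.shape[0]
    if n < 2:
        return np.nan
    diffs = [int(np.sum(H[i] != H[j])) for i, j in combinations(range(n), 2)]
    return sum(diffs) / len(diffs)


def trapezoid_ihh(points, cutoff=0.05):
    """Hand trapezoid over an explicit (distance, EHH) curve, stopping with
    a partial trapezoid at the linear-interpolated cutoff crossing."""
    area = 0.0
    for (x0, e0), (x1, e1) in zip(points, points[1:]):
        if e1 < cutoff:
            if e0 > cutoff:
                xc = x0 + (e0 - cutoff) / (e0 - e1) * (x1 - x0)
                area += 0.5 * (e0 + cutoff) * (xc - x0)
            break
        area += 0.5 * (e0 + e1) * (x1 - x0)
    return area


def nearest_gene_brute(position, genes):
    """(distance, accession) of the nearest gene body by linear search."""
    best = None
    for g in genes:
        if position < g.start:
            d = g.start - position
        elif position >= g.stop:
            d = position - g.stop + 1
        else:
            d = 0
        if best is None or d < best[0]:
            best = (d, g.accession)
    return best
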