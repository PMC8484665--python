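"""Numba kernels for Li-Stephens haplotype painting.

Scaled forward-backward over a hidden copying path: at each site the
recipient haplotype copies from one donor haplotype; between adjacent sites
the path switches donor with probability 1 - exp(-rho * d) (d = bp span),
landing uniformly on the donor pool; emissions match the donor allele with
probability 1 - mu. Donor haplotypes belonging to the recipient's own
individual are excluded from the pool.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def paint_one(rec, haps, donors, positions, spans, rho, mu):
    """Forward-backward for one recipient haplotype.

    Returns (expected copied length per donor, log-likelihood,
    expected switch count).
    """
    L = positions.shape[0]
    K = donors.shape[0]
    alpha = np.empty((L, K))
    c = np.empty(L)
    a = np.empty(K)
    for k in range(K):
        e = (1.0 - mu) if haps[donors[k], 0] == rec[0] else mu
        a[k] = e / K
    s = a.sum()
    c[0] = s
    alpha[0] = a / s
    loglik = np.log(s)
    for l in range(1, L):
        d = positions[l] - positions[l - 1]
        pj = 1.0 - np.exp(-rho * d)
        prev_mass = pj / K  # alpha rows are normalized to 1
        for k in range(K):
            e = (1.0 - mu) if haps[donors[k], l] == rec[l] else mu
            a[k] = e * ((1.0 - pj) * alpha[l - 1, k] + prev_mass)
        s = a.sum()
        c[l] = s
        alpha[l] = a / s
        loglik += np.log(s)
    # Backward pass, scaled by the forward normalizers.
    b = np.ones(K)
    lengths = np.zeros(K)
    g = np.empty(K)
    e_switches = 0.0
    for k in range(K):
        lengths[k] += alpha[L - 1, k] * spans[L - 1]
    for l in range(L - 2, -1, -1):
        d = positions[l + 1] - positions[l]
        pj = 1.0 - np.exp(-rho * d)
        eb = np.empty(K)
        ebsum = 0.0
        for k in range(K):
            e = (1.0 - mu) if haps[donors[k], l + 1] == rec[l + 1] else mu
            eb[k] = e * b[k]
            ebsum += eb[k]
        # Probability the path keeps the same donor (no jump, or a jump
        # landing back on it); its complement counts donor changes only.
        stay = 0.0
        for k in range(K):
            stay += alpha[l, k] * ((1.0 - pj) + pj / K) * eb[k]
        stay /= c[l + 1]
        e_switches += 1.0 - stay
        for k in range(K):
            b[k] = ((1.0 - pj) * eb[k] + pj * ebsum / K) / c[l + 1]
        gs = 0.0
        for k in range(K):
            g[k] = alpha[l, k] * b[k]
            gs += g[k]
        for k in range(K):
            lengths[k] += g[k] / gs * spans[l]
    return lengths, loglik, e_switches


@njit(cache=True)
def paint_all(haps, sample_of_hap, positions, spans, rho, mu):
    """Paint every haplotype against all other individuals' haplotypes.

    Returns (lengths[donor_individual, recipient_individual], total
    log-likelihood, total expected switches).
    """
    n_hap = haps.shape[0]
    n_ind = n_hap // 2
    out = np.zeros((n_ind, n_ind))
    total_ll = 0.0
    total_sw = 0.0
    donors = np.empty(n_hap - 2, dtype=np.int64)
    for h in range(n_hap):
        ind = sample_of_hap[h]
        j = 0
        for d in range(n_hap):
            if sample_of_hap[d] != ind:
                donors[j] = d
                j += 1
        lengths, ll, sw = paint_one(
            haps[h], haps, donors, positions, spans, rho, mu
        )
        total_ll += ll
        total_sw += sw
        for k in range(donors.shape[0]):
            out[sample_of_hap[donors[k]], ind] += lengths[k]
    return out, total_ll, total_sw
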