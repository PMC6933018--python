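"""Independent oracle implementations used only for cross-checking.

These are deliberately written as literal, loop-based transcriptions of the
published formulas (general number of populations r), sharing no code with
the vectorized implementations they validate.
"""

from __future__ import annotations

import numpy as np


def wc_theta_reference(pop_genotypes: list[np.ndarray]) -> float:
    """Weir & Cockerham theta-hat from per-population genotype matrices.

    ``pop_genotypes`` is a list of (individuals x loci) dosage arrays
    (codes 0/1/2, -1 missing), one per population. Returns the ratio-of-sums
    estimate over loci segregating in the pooled sample.
    """
    r = len(pop_genotypes)
    L = pop_genotypes[0].shape[1]
    num = 0.0
    den = 0.0
    for l in range(L):
        ns, ps, hs = [], [], []
        for G in pop_genotypes:
            col = G[:, l]
            called = col[col >= 0]
            if len(called) == 0:
                ns.append(0)
                ps.append(0.0)
                hs.append(0.0)
                continue
            ns.append(len(called))
            ps.append(float(np.sum(called)) / (2 * len(called)))
            hs.append(float(np.mean(called == 1)))
        if any(n == 0 for n in ns):
            continue
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        if pbar <= 0 or pbar >= 1:
            continue
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2 * nbar - 1) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
        num += a
        den += a + b + c
    if den == 0:
        raise ValueError("no usable loci")
    return num / den


def pca_eigenvalues_reference(X: np.ndarray) -> np.ndarray:
    """Eigenvalues of the sample covariance matrix of a complete data matrix."""
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    vals = np.linalg.eigvalsh(cov)
    return np.sort(vals)[::-1]
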