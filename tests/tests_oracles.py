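"""Brute-force reference implementations used as independent oracles.

These deliberately use explicit loops and set constructions so they share no
code path with the package implementations they check.
"""

import numpy as np


def brute_entropy(m, bins):
    m = np.asarray(m, dtype=float).ravel()
    lo, hi = m.min(), m.max()
    if hi == lo:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    h = 0.0
    for i in range(bins):
        if i < bins - 1:
            c = np.sum((m >= edges[i]) & (m < edges[i + 1]))
        else:
            c = np.sum((m >= edges[i]) & (m <= edges[i + 1]))
        p = c / m.size
        if p > 0:
            h -= p * np.log2(p)
    return h


def kapur_psi_profile(m, bins=256):
    """psi(t) = H_background + H_foreground at every candidate level,
    evaluated by explicit per-threshold summation."""
    m = np.asarray(m, dtype=float).ravel()
    counts, edges = np.histogram(m, bins=bins, range=(m.min(), m.max()))
    p = counts / counts.sum()
    psi = np.full(bins - 1, -np.inf)
    for t in range(bins - 1):
        p0, p1 = p[: t + 1].sum(), p[t + 1 :].sum()
        if p0 <= 0 or p1 <= 0:
            continue
        q0 = p[: t + 1][p[: t + 1] > 0] / p0
        q1 = p[t + 1 :][p[t + 1 :] > 0] / p1
        psi[t] = -(q0 * np.log(q0)).sum() - (q1 * np.log(q1)).sum()
    return psi, edges


def brute_kapur(m, bins=256):
    psi, edges = kapur_psi_profile(m, bins)
    return float(edges[int(np.argmax(psi)) + 1])


def kapur_attains_oracle_max(threshold, m, bins=256, tol=1e-9):
    """True when `threshold` sits at a global maximizer of the exhaustively
    evaluated psi profile (robust to exact ties, where any maximizer is
    equally correct)."""
    psi, edges = kapur_psi_profile(m, bins)
    t = int(np.searchsorted(edges, threshold)) - 1
    return psi[t] >= psi.max() - tol


def brute_jaccard(a, b):
    sa = {(i, s) for i, s in enumerate(a)}
    sb = {(i, s) for i, s in enumerate(b)}
    return len(sa & sb) / len(a)
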