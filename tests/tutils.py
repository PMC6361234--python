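"""Shared helpers and independent oracles for the test suite."""

from itertools import combinations

import numpy as np

from smssvd import DataMatrix


def random_datamatrix(p, n, seed, rank=None):
    """Seeded random matrix, optionally of exact (numerical) rank."""
    rng = np.random.default_rng(seed)
    if rank is None:
        values = rng.standard_normal((p, n))
    else:
        values = rng.standard_normal((p, rank)) @ rng.standard_normal((rank, n))
    return DataMatrix(values)


def svd_oracle(values):
    """Dense SVD oracle (thin), independent of the package internals."""
    return np.linalg.svd(values, full_matrices=False)


def rank_oracle(values, rtol=1e-12, ref=None):
    """Singular-value counting rank; ``ref`` supplies an absolute scale
    (e.g. the largest singular value of the pre-deflation matrix)."""
    s = np.linalg.svd(values, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    scale = ref if ref is not None else s[0]
    return int(np.count_nonzero(s > rtol * scale))


def rowspace_basis(values, d, seed):
    """Orthonormal basis of a random d-dim subspace of the row space of X.

    Guaranteed orthogonal to ker X, as the restricted-SVD precondition
    requires.
    """
    rng = np.random.default_rng(seed)
    u, s, vt = svd_oracle(values)
    r = rank_oracle(values)
    assert d <= r
    mix = vt[:r].T @ rng.standard_normal((r, d))
    q, _ = np.linalg.qr(mix)
    return q


def brute_force_match_error(components, signals):
    """Exhaustive minimum total support-restricted error over all
    capacity-respecting assignments of components to signals."""
    caps = [s.rank for s in signals]
    targets = [s.Y[s.support] for s in signals]
    comp_on_support = [
        [sigma * np.outer(u[s.support], v) for s in signals]
        for (u, sigma, v) in components
    ]
    best = [np.inf]

    def rec(k, avail, err_sum):
        if err_sum >= best[0]:
            return
        if k == len(signals):
            best[0] = min(best[0], err_sum)
            return
        for subset in combinations(sorted(avail), caps[k]):
            recon = np.zeros_like(targets[k])
            for c in subset:
                recon += comp_on_support[c][k]
            err = float(np.linalg.norm(targets[k] - recon))
            rec(k + 1, avail - set(subset), err_sum + err)

    rec(0, set(range(len(components))), 0.0)
    return best[0]
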