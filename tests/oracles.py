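"""Independent brute-force oracles used by the tests.

These deliberately re-derive quantities by enumeration or direct arithmetic,
sharing no code path with the package implementation they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def chain_matrices(cluster_anc: np.ndarray, n_upper: int, u: float, v: float,
                   pi_row: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dense transition matrix and initial distribution of the layered chain.

    Built state-by-state from the model definition: with probability u the
    ancestry is redrawn from the admixture proportions and a cluster drawn
    uniformly within it; otherwise, with probability v the cluster is redrawn
    within the current ancestry; otherwise the state is kept.
    """
    C = len(cluster_anc)
    counts = np.bincount(cluster_anc, minlength=n_upper)
    w = 1.0 / counts[cluster_anc]
    pstar = pi_row[cluster_anc] * w
    T = np.empty((C, C))
    for j in range(C):
        for k in range(C):
            same = cluster_anc[j] == cluster_anc[k]
            T[j, k] = (u * pstar[k]
                       + (1 - u) * (same * v * w[k] + (1 - v) * (j == k)))
    return T, pstar


def enumerate_haploid(theta, cluster_anc, n_upper, u, v, pi_row, hap):
    """Exhaustive-path posterior cluster marginals and log-likelihood for one
    haplotype (missing sites coded -1 emit nothing)."""
    M, C = theta.shape
    Ts = [chain_matrices(cluster_anc, n_upper, u[m], v[m], pi_row)[0]
          for m in range(M - 1)]
    _, pstar = chain_matrices(cluster_anc, n_upper, u[0] if len(u) else 0.0,
                              v[0] if len(v) else 0.0, pi_row)

    def emit(m, j):
        if hap[m] < 0:
            return 1.0
        return theta[m, j] if hap[m] == 1 else 1.0 - theta[m, j]

    total = 0.0
    marg = np.zeros((M, C))
    for path in itertools.product(range(C), repeat=M):
        p = pstar[path[0]] * emit(0, path[0])
        for m in range(1, M):
            p *= Ts[m - 1][path[m - 1], path[m]] * emit(m, path[m])
        total += p
        for m in range(M):
            marg[m, path[m]] += p
    return marg / total, np.log(total)


def enumerate_diploid(theta, cluster_anc, n_upper, u, v, pi_row, geno):
    """Exhaustive enumeration over ordered pairs of cluster paths for one
    diplotype, with phase integrated out of the emissions (NaN = missing)."""
    M, C = theta.shape
    Ts = [chain_matrices(cluster_anc, n_upper, u[m], v[m], pi_row)[0]
          for m in range(M - 1)]
    _, pstar = chain_matrices(cluster_anc, n_upper, u[0] if len(u) else 0.0,
                              v[0] if len(v) else 0.0, pi_row)

    def emit(m, j, k):
        g = geno[m]
        if np.isnan(g):
            return 1.0
        t1, t2 = theta[m, j], theta[m, k]
        if g == 0:
            return (1 - t1) * (1 - t2)
        if g == 1:
            return t1 * (1 - t2) + (1 - t1) * t2
        return t1 * t2

    total = 0.0
    marg = np.zeros((M, C))
    for pa in itertools.product(range(C), repeat=M):
        for pb in itertools.product(range(C), repeat=M):
            p = pstar[pa[0]] * pstar[pb[0]]
            for m in range(1, M):
                p *= Ts[m - 1][pa[m - 1], pa[m]] * Ts[m - 1][pb[m - 1], pb[m]]
            for m in range(M):
                p *= emit(m, pa[m], pb[m])
            total += p
            for m in range(M):
                marg[m, pa[m]] += 0.5 * p
                marg[m, pb[m]] += 0.5 * p
    return marg / total, np.log(total)


def theta_unweighted(q: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """The equal-weight cluster allele-frequency estimator: at each marker,
    the posterior mass of allele-1 carriers over the total posterior mass."""
    num = (q * (alleles == 1)[:, :, None]).sum(axis=0)
    den = (q * (alleles >= 0)[:, :, None]).sum(axis=0)
    return num / den
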