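"""Independent brute-force oracles for the test suite.

These deliberately avoid the package's column-reduction pairing algorithm:
persistence pairs are recovered from persistent Betti numbers
beta_k(r_i, r_j) = dim im(H_k(K_i) -> H_k(K_j)) computed by plain GF(2)
linear algebra (kernel bases via row-reduced echelon form, subspace sums
via incremental rank), and the diagram Wasserstein distance is recovered
by exhaustive enumeration of all partial matchings.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------- GF(2) ranks

def _rref_nullspace(mat: np.ndarray) -> list[int]:
    """Null-space basis of a GF(2) matrix (rows x cols), as column bitmasks."""
    m = (mat.copy() % 2).astype(np.uint8)
    rows, cols = m.shape
    pivots = []
    r = 0
    for c in range(cols):
        if r >= rows:
            break
        hit = np.flatnonzero(m[r:, c]) + r
        if hit.size == 0:
            continue
        if hit[0] != r:
            m[[r, hit[0]]] = m[[hit[0], r]]
        other = np.flatnonzero(m[:, c])
        other = other[other != r]
        m[other] ^= m[r]
        pivots.append(c)
        r += 1
    free = [c for c in range(cols) if c not in pivots]
    basis = []
    for f in free:
        vec = 1 << f
        for prow, pcol in enumerate(pivots):
            if m[prow, f]:
                vec |= 1 << pcol
        basis.append(vec)
    return basis


class _IncrementalRank:
    """Rank of a growing set of GF(2) vectors (int bitmasks)."""

    def __init__(self, vectors=()):
        self.pivots: dict[int, int] = {}
        self.rank = 0
        for v in vectors:
            self.add(v)

    def add(self, vec: int) -> None:
        while vec:
            low = vec.bit_length() - 1
            p = self.pivots.get(low)
            if p is None:
                self.pivots[low] = vec
                self.rank += 1
                return
            vec ^= p


# ------------------------------------------------- brute-force persistence

def _all_simplices(n: int, half: np.ndarray, max_simplex_dim: int):
    """Every simplex up to max_simplex_dim with its half-diameter radius."""
    out = {0: ([(v,) for v in range(n)], [0.0] * n)}
    for k in range(1, max_simplex_dim + 1):
        simp, fv = [], []
        for s in combinations(range(n), k + 1):
            f = max(half[a][b] for a, b in combinations(s, 2))
            simp.append(s)
            fv.append(f)
        order = sorted(range(len(simp)), key=lambda i: (fv[i], simp[i]))
        out[k] = ([simp[i] for i in order], [fv[i] for i in order])
    return out


def bruteforce_diagram(points: np.ndarray, max_hom_dim: int = 2):
    """Multiset of (dim, birth, death) pairs of the full Rips filtration.

    ``death = inf`` marks essential classes.  Zero-persistence pairs are
    not reported.  Complexity is exponential in the number of points; use
    only on tiny clouds.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    half = squareform(pdist(points)) / 2.0 if n > 1 else np.zeros((1, 1))
    complexes = _all_simplices(n, half, max_hom_dim + 1)
    crit = sorted({0.0} | {f for k in complexes for f in complexes[k][1]})
    R = len(crit)

    pairs = []
    for k in range(max_hom_dim + 1):
        simp_k, fv_k = complexes[k]
        faces_idx = {s: i for i, s in enumerate(complexes[k - 1][0])} if k else None
        n_k_at = [sum(1 for f in fv_k if f <= r) for r in crit]

        # kernel bases Z_k(i) for each critical index
        boundary_rows = len(complexes[k - 1][0]) if k else 0
        Z: list[list[int]] = []
        for i, r in enumerate(crit):
            m_cols = n_k_at[i]
            if k == 0:
                Z.append([1 << c for c in range(m_cols)])
                continue
            mat = np.zeros((boundary_rows, m_cols), dtype=np.uint8)
            for c in range(m_cols):
                for face in combinations(simp_k[c], k):
                    mat[faces_idx[face], c] ^= 1
            Z.append(_rref_nullspace(mat))

        # boundary columns of (k+1)-simplices as bitmasks over k-simplices
        simp_k1, fv_k1 = complexes.get(k + 1, ([], []))
        simp_idx = {s: i for i, s in enumerate(simp_k)}
        bcols = []
        for s in simp_k1:
            bits = 0
            for face in combinations(s, k + 1):
                bits ^= 1 << simp_idx[face]
            bcols.append(bits)

        dimB = []
        inc = _IncrementalRank()
        ptr = 0
        for r in crit:
            while ptr < len(bcols) and fv_k1[ptr] <= r:
                inc.add(bcols[ptr])
                ptr += 1
            dimB.append(inc.rank)

        # beta[i][j] = dim(Z_k(i) + B_k(j)) - dim B_k(j), j >= i
        beta = np.zeros((R, R))
        for i in range(R):
            inc = _IncrementalRank(Z[i])
            ptr = 0
            for j in range(i, R):
                while ptr < len(bcols) and fv_k1[ptr] <= crit[j]:
                    inc.add(bcols[ptr])
                    ptr += 1
                beta[i, j] = inc.rank - dimB[j]

        def b(i, j):
            return beta[i, j] if (0 <= i < R and 0 <= j < R and j >= i) else 0.0

        for i in range(R):
            for j in range(i + 1, R):
                mult = b(i, j - 1) - b(i, j) - b(i - 1, j - 1) + b(i - 1, j)
                for _ in range(int(round(mult))):
                    pairs.append((k, crit[i], crit[j]))
            mult = b(i, R - 1) - b(i - 1, R - 1)
            for _ in range(int(round(mult))):
                pairs.append((k, crit[i], np.inf))
    return pairs


# ------------------------------------------------- brute-force Wasserstein

def _supnorm(p, q):
    return max(abs(p[0] - q[0]), abs(p[1] - q[1]))


def bruteforce_wasserstein(P1, P2, q: float = 2.0) -> float:
    """Exhaustive minimum over all partial matchings (<= ~5 points a side)."""
    P1 = [tuple(p) for p in np.asarray(P1, dtype=float).reshape(-1, 2)]
    P2 = [tuple(p) for p in np.asarray(P2, dtype=float).reshape(-1, 2)]
    d1 = [(d - b) / 2.0 for b, d in P1]
    d2 = [(d - b) / 2.0 for b, d in P2]
    n, m = len(P1), len(P2)
    best = np.inf
    for k in range(min(n, m) + 1):
        for s1 in combinations(range(n), k):
            for s2 in permutations(range(m), k):
                cost = sum(_supnorm(P1[a], P2[b]) ** q for a, b in zip(s1, s2))
                cost += sum(d1[a] ** q for a in range(n) if a not in s1)
                cost += sum(d2[b] ** q for b in set(range(m)) - set(s2))
                best = min(best, cost)
    return float(best ** (1.0 / q))
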