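"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation paths they check: recursive
enumeration instead of itertools.product, exhaustive subset search instead of
PAM, and a direct O(n^3) agglomeration instead of scipy's linkage.
"""

from __future__ import annotations

import itertools

import numpy as np

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def enumerate_consensus(consensus: str) -> list[str]:
    """Recursive expansion of a degenerate consensus (sorted, unique)."""
    if not consensus:
        return [""]
    rest = enumerate_consensus(consensus[1:])
    return sorted(b + tail for b in IUPAC[consensus[0]] for tail in rest)


def kmedoids_optimum(D: np.ndarray, k: int) -> float:
    """Exact optimum of the k-medoids objective by exhaustive search."""
    n = D.shape[0]
    best = np.inf
    for subset in itertools.combinations(range(n), k):
        cost = D[list(subset)].min(axis=0).sum()
        best = min(best, cost)
    return float(best)


def complete_linkage_heights(X: np.ndarray) -> list[float]:
    """Merge heights of complete-linkage agglomeration on Euclidean distances.

    Direct O(n^3) implementation: repeatedly merge the two clusters with the
    smallest maximum pairwise point distance.
    """
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters: list[list[int]] = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                h = max(D[i, j] for i in clusters[a] for j in clusters[b])
                if h < best[0]:
                    best = (h, (a, b))
        h, (a, b) = best
        heights.append(h)
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return heights
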