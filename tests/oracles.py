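"""Independent brute-force oracles shared by the metric tests.

These deliberately avoid the implementation's code paths: rarefaction by
exhaustive subset enumeration, FEve from its defining formula over a
networkx Kruskal spanning tree, FDis by plain loops.
"""

import itertools

import networkx as nx
import numpy as np


def rarefied_richness_by_enumeration(abundances, n):
    """Average species count over every possible n-subset of individuals."""
    individuals = [sp for sp, k in enumerate(abundances) for _ in range(int(k))]
    species_counts = [len(set(c)) for c in itertools.combinations(individuals, n)]
    return float(np.mean(species_counts))


def feve_bruteforce(traits, abundances):
    """FEve from its defining formula with a networkx Kruskal MST."""
    x = np.asarray(traits, dtype=float)
    a = np.asarray(abundances, dtype=float)
    s = len(a)
    w = a / a.sum()
    g = nx.Graph()
    for i in range(s):
        for j in range(i + 1, s):
            g.add_edge(i, j, weight=float(np.linalg.norm(x[i] - x[j])))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    ew = []
    for i, j in mst.edges():
        d = float(np.linalg.norm(x[i] - x[j]))
        ew.append(d / (w[i] + w[j]))
    ew = np.array(ew)
    pew = ew / ew.sum()
    thr = 1.0 / (s - 1)
    return (np.minimum(pew, thr).sum() - thr) / (1.0 - thr)


def fdis_bruteforce(traits, abundances):
    """Plain-loop abundance-weighted distance to the weighted centroid."""
    x = np.asarray(traits, dtype=float)
    a = np.asarray(abundances, dtype=float)
    centroid = np.zeros(x.shape[1])
    for i in range(len(a)):
        centroid += a[i] * x[i]
    centroid /= a.sum()
    num = sum(a[i] * np.linalg.norm(x[i] - centroid) for i in range(len(a)))
    return num / a.sum()


def integer_partitions(n, max_part=None):
    """All multisets of positive integers summing to n (species abundance shapes)."""
    max_part = n if max_part is None else max_part
    if n == 0:
        yield ()
        return
    for first in range(min(n, max_part), 0, -1):
        for rest in integer_partitions(n - first, first):
            yield (first,) + rest
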