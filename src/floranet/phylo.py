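"""Alignment-free composition-vector phylogenetics.

Per-taxon K-tuple frequencies (default K = 6, amino-acid alphabet) are
corrected by subtracting a Markov background predicted from the (K-1)- and
(K-2)-tuple frequencies of the same sequences; the normalized deviations
form the composition vector. Pairwise distances are D = (1 - C) / 2 with C
the cosine similarity over the union of tuple keys, and trees are built by
neighbor joining (UPGMA available as an alternative).

Windows containing a character outside the declared alphabet are not
counted, and windows never span sequence boundaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .properties import AMINO_ACIDS


def count_tuples(
    sequences: list[str], k: int, alphabet: str = AMINO_ACIDS
) -> tuple[dict[str, int], dict[str, float]]:
    """Overlapping K-tuple counts and frequencies over a taxon's sequences.

    Returns (counts, frequencies); frequencies divide by the total number
    of valid windows.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    valid = set(alphabet)
    counts: Counter[str] = Counter()
    any_window = False
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if set(window) <= valid:
                counts[window] += 1
                any_window = True
    if not any_window:
        raise ValueError(f"no sequence admits a window of length {k}")
    total = sum(counts.values())
    freqs = {t: c / total for t, c in counts.items()}
    return dict(counts), freqs


@dataclass
class CompositionProfile:
    """Background-subtracted K-tuple vector for one taxon."""

    taxon: str
    k: int
    components: dict[str, float]


def background_subtract(
    freq_k: dict[str, float],
    freq_k1: dict[str, float],
    freq_k2: dict[str, float],
    k: int,
    taxon: str = "",
) -> CompositionProfile:
    """Normalized deviation from the Markov-predicted tuple frequencies.

    The background prediction for tuple s1..sk is
    a0 = f(s1..s_{k-1}) * f(s2..s_k) / f(s2..s_{k-1});
    the stored component is a = (f - a0) / a0 wherever a0 > 0 (tuples that
    are predicted but unobserved therefore get -1). Tuples with a0 = 0
    contribute 0 and are omitted.
    """
    if k < 3:
        raise ValueError("background subtraction needs k-2 tuples (k >= 3)")
    # candidate tuples: every left extension x+core joined with every right
    # extension core+y over the observed (k-1)-mers
    lefts: dict[str, list[str]] = {}
    rights: dict[str, list[str]] = {}
    for w in freq_k1:
        lefts.setdefault(w[1:], []).append(w)
        rights.setdefault(w[:-1], []).append(w)
    components: dict[str, float] = {}
    for core, f_core in freq_k2.items():
        if f_core <= 0:
            continue
        for left in lefts.get(core, ()):
            for right in rights.get(core, ()):
                tup = left + right[-1]
                a0 = freq_k1[left] * freq_k1[right] / f_core
                if a0 > 0:
                    f = freq_k.get(tup, 0.0)
                    components[tup] = (f - a0) / a0
    return CompositionProfile(taxon=taxon, k=k, components=components)


def composition_profile(
    taxon: str, sequences: list[str], k: int = 6, alphabet: str = AMINO_ACIDS
) -> CompositionProfile:
    """Count K, K-1 and K-2 tuples from the same sequences and subtract."""
    _, fk = count_tuples(sequences, k, alphabet)
    _, fk1 = count_tuples(sequences, k - 1, alphabet)
    _, fk2 = count_tuples(sequences, k - 2, alphabet)
    return background_subtract(fk, fk1, fk2, k, taxon=taxon)


def cv_distance(p1: CompositionProfile, p2: CompositionProfile) -> float:
    """D = (1 - C) / 2 with C the cosine over the union of tuple keys."""
    if p1.k != p2.k:
        raise ValueError("profiles must share the same K")
    keys = set(p1.components) | set(p2.components)
    a1 = np.array([p1.components.get(t, 0.0) for t in sorted(keys)])
    a2 = np.array([p2.components.get(t, 0.0) for t in sorted(keys)])
    n1 = np.linalg.norm(a1)
    n2 = np.linalg.norm(a2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate composition vector")
    c = float(a1 @ a2 / (n1 * n2))
    return float(np.clip((1.0 - c) / 2.0, 0.0, 1.0))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape must match the taxa list")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(m, 0.0)
        self.matrix = m


def build_distance_matrix(profiles: list[CompositionProfile]) -> DistanceMatrix:
    taxa = [p.taxon for p in profiles]
    n = len(profiles)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = cv_distance(profiles[i], profiles[j])
    return DistanceMatrix(taxa=taxa, matrix=m)


def _fmt(x: float) -> str:
    return f"{max(0.0, x):.6f}"


def neighbor_joining(dist: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Negative branch lengths are clamped to zero and ties in the Q
    criterion are broken by the lexicographically smallest taxon pair, so
    the output is deterministic.
    """
    n = len(dist.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dist.matrix.astype(float).copy()
    nodes = list(dist.taxa)  # Newick fragment per active node
    names = list(dist.taxa)  # lexicographic keys for tie-breaking
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((names[i], names[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        new_node = f"({nodes[i]}:{_fmt(li)},{nodes[j]}:{_fmt(lj)})"
        new_name = min(names[i], names[j])
        d_new = np.array(
            [(d[i, t] + d[j, t] - d[i, j]) / 2.0 for t in range(m) if t not in (i, j)]
        )
        keep = [t for t in range(m) if t not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = d_new
        d[:-1, -1] = d_new
        nodes = [nodes[t] for t in keep] + [new_node]
        names = [names[t] for t in keep] + [new_name]
    # terminal star of three nodes
    la = (d[0, 1] + d[0, 2] - d[1, 2]) / 2.0
    lb = (d[0, 1] + d[1, 2] - d[0, 2]) / 2.0
    lc = (d[0, 2] + d[1, 2] - d[0, 1]) / 2.0
    order = sorted(range(3), key=lambda t: names[t])
    lengths = {0: la, 1: lb, 2: lc}
    parts = [f"{nodes[t]}:{_fmt(lengths[t])}" for t in order]
    return f"({parts[0]},{parts[1]},{parts[2]});"


def upgma(dist: DistanceMatrix) -> str:
    """Average-linkage (UPGMA) rooted tree as Newick."""
    n = len(dist.taxa)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    active: dict[int, tuple[str, float, int, str]] = {
        i: (dist.taxa[i], 0.0, 1, dist.taxa[i]) for i in range(n)
    }  # id -> (newick fragment, height, size, lexicographic key)
    d = {
        (i, j): dist.matrix[i, j] for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), val in d.items():
            if i in active and j in active:
                key = (val, *sorted((active[i][3], active[j][3])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        val = d[(i, j)]
        height = val / 2.0
        fi, hi, si, ki = active[i]
        fj, hj, sj, kj = active[j]
        frag = f"({fi}:{_fmt(height - hi)},{fj}:{_fmt(height - hj)})"
        new_key = min(ki, kj)
        for t in list(active):
            if t in (i, j):
                continue
            dti = d[tuple(sorted((t, i)))]
            dtj = d[tuple(sorted((t, j)))]
            d[tuple(sorted((t, next_id)))] = (si * dti + sj * dtj) / (si + sj)
        del active[i], active[j]
        active[next_id] = (frag, height, si + sj, new_key)
        next_id += 1
    (frag, _, _, _) = next(iter(active.values()))
    return f"{frag};"


def build_tree(dist: DistanceMatrix, method: str = "nj") -> str:
    if method == "nj":
        return neighbor_joining(dist)
    if method == "upgma":
        return upgma(dist)
    raise ValueError("method must be 'nj' or 'upgma'")
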