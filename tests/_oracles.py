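"""Independent brute-force oracles used to cross-check the implementation."""

from itertools import product

import numpy as np


_PATH_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _all_paths(n_states, length):
    key = (n_states, length)
    if key not in _PATH_CACHE:
        _PATH_CACHE[key] = np.array(
            list(product(range(n_states), repeat=length)), dtype=np.int8
        )
    return _PATH_CACHE[key]


def viterbi_exhaustive(values, params):
    """Best state path by scoring every one of the 5^L paths (L must be small).

    Ties resolve to the lexicographically smallest path, matching the
    documented lower-state tie-break of the dynamic program.
    """
    means = np.asarray(params.emission_means)
    sds = np.asarray(params.emission_sds)
    loga = np.log(params.transition_matrix())
    logpi = np.log(np.asarray(params.initial))
    length = len(values)
    logb = np.zeros((length, len(means)))
    for t, v in enumerate(values):
        if not np.isnan(v):
            logb[t] = -0.5 * ((v - means) / sds) ** 2 - np.log(sds)
    paths = _all_paths(len(means), length)  # (5^L, L), lexicographic order
    scores = logpi[paths[:, 0]] + logb[np.arange(length), paths].sum(axis=1)
    if length > 1:
        scores += loga[paths[:, :-1], paths[:, 1:]].sum(axis=1)
    # argmax returns the first (lexicographically smallest) maximizer
    best = int(np.argmax(scores > scores.max() - 1e-12))
    return paths[best].astype(np.int64)


def quantile_cutoffs_bruteforce(values, n_buckets):
    """Sort values and split into n equal runs; cutoffs are the run maxima."""
    v = sorted(x for x in values if not np.isnan(x))
    m = len(v)
    out = []
    for k in range(1, n_buckets):
        idx = int(np.ceil(k * m / n_buckets)) - 1
        out.append(v[idx])
    return np.array(out)


def bucket_bruteforce(gc, cutoffs):
    """Scan the half-open quantile intervals one by one."""
    for i, c in enumerate(cutoffs):
        if gc <= c:
            return i
    return len(cutoffs)


def single_linkage_bruteforce(positions, cutoff):
    """Quadratic agglomeration: merge any two clusters with members <= cutoff apart."""
    clusters = [[p] for p in positions]
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(
                    abs(a - b) <= cutoff for a in clusters[i] for b in clusters[j]
                ):
                    clusters[i] += clusters.pop(j)
                    merged = True
                    break
            if merged:
                break
    return sorted(tuple(sorted(c)) for c in clusters)


def child_states_bruteforce(father, mother):
    """Enumerate transmitted haplotype copy counts for both parents."""
    transmit = {0: [0], 1: [0, 1], 2: [1], 3: [1, 2], 4: [2, 3]}
    return frozenset(
        min(a + b, 4) for a in transmit[father] for b in transmit[mother]
    )
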