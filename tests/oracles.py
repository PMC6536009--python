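"""Independent reference implementations used to cross-check the package.

These deliberately re-derive results from first principles (exhaustive
enumeration, definition-level set manipulation) rather than sharing code
with the implementation under test.
"""

import itertools

import numpy as np


def enumerate_affinity_p(K, background, threshold):
    """P(total lattice score >= threshold) by brute-force enumeration of
    every sequence of the motif's length, weighted by the background."""
    K = np.asarray(K)
    L = K.shape[0]
    total = 0.0
    for seq in itertools.product(range(4), repeat=L):
        score = sum(K[i, b] for i, b in enumerate(seq))
        if score >= threshold:
            total += float(np.prod([background[b] for b in seq]))
    return total


def enumerate_best_score(K, seq_indices, snp_pos):
    """Best lattice score over windows covering snp_pos, both strands, by
    direct enumeration (no shared scanning code)."""
    K = np.asarray(K)
    L = K.shape[0]
    scores = []
    for o in range(len(seq_indices) - L + 1):
        if not (o <= snp_pos < o + L):
            continue
        window = seq_indices[o:o + L]
        scores.append(sum(K[i, b] for i, b in enumerate(window)))
        revcomp = [3 - b for b in reversed(window)]
        scores.append(sum(K[i, b] for i, b in enumerate(revcomp)))
    return max(scores)


def brute_force_clumps(p_values, r2_lookup, r2_threshold, p_threshold):
    """Clump assignment re-derived from the definition.

    ``p_values``: {snp: p}; ``r2_lookup``: callable (a, b) -> r^2.
    Returns a list of (index_snp, frozenset(members)) ordered by index p.
    """
    remaining = {s for s, p in p_values.items() if p < p_threshold}
    clumps = []
    while remaining:
        index = min(remaining, key=lambda s: (p_values[s], s))
        members = frozenset(
            s for s in remaining if r2_lookup(index, s) >= r2_threshold
        )
        clumps.append((index, members))
        remaining -= members
    return clumps
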