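"""Independent brute-force oracles used only by the test suite.

Each is a deliberately naive implementation kept separate from the library
code paths it validates: a quadratic affine-gap Smith-Waterman matrix fill,
exhaustive small-parsimony by enumerating all internal-node assignments, and
a Mann-Whitney two-tailed p by enumerating group assignments of the data.
"""

import itertools
import math

NEG = -math.inf


def sw_score(query: str, subject: str, match=2.0, mismatch=-3.0,
             gap_open=-5.0, gap_extend=-2.0) -> float:
    """Best local alignment score; a gap of length L costs
    gap_open + (L-1)*gap_extend.  N never matches anything."""
    n, m = len(query), len(subject)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (query consumed)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    best = 0.0
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            s = match if (qi == subject[j - 1] and qi != "N") else mismatch
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def exhaustive_parsimony(parent: dict, leaves: dict, states) -> int:
    """Minimum changes over all assignments of states to internal nodes.

    ``parent`` maps child -> parent over all nodes (root maps to None);
    ``leaves`` maps leaf node -> fixed state.
    """
    internal = sorted(
        {p for p in parent.values() if p is not None}
        | {n for n in parent if n not in leaves and parent[n] is not None},
        key=str,
    )
    internal = [n for n in internal if n not in leaves]
    edges = [(c, p) for c, p in parent.items() if p is not None]
    best = math.inf
    for combo in itertools.product(states, repeat=len(internal)):
        assign = dict(zip(internal, combo))
        assign.update(leaves)
        changes = sum(1 for c, p in edges if assign[c] != assign[p])
        best = min(best, changes)
    return int(best)


def mwu_exact_p(x, y) -> float:
    """Two-tailed Mann-Whitney p by enumerating all assignments of the
    pooled data into groups of sizes (|x|, |y|), computing U from the data
    values themselves (count of (xi > yj) pairs + half-ties)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(group_a, group_b):
        u = 0.0
        for a in group_a:
            for b in group_b:
                if a > b:
                    u += 1.0
                elif a == b:
                    u += 0.5
        return u

    mu = n1 * len(y) / 2
    obs = abs(u_of(x, y) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_of(ga, gb) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total
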