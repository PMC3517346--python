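"""Naive reference implementations used only by the test suite.

Written independently of the package internals: plain-python dynamic
programming for local alignment, explicit subset enumeration for hit
chaining, and exhaustive labeling for small-parsimony counts.
"""

from itertools import combinations, product


def gotoh_local_score(a, b, matrix, alphabet_index, gap_open, gap_extend):
    """Quadratic plain-python affine-gap Smith-Waterman score."""
    ea = [alphabet_index[c] for c in a]
    eb = [alphabet_index[c] for c in b]
    NEG = float("-inf")
    n, m = len(ea), len(eb)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0)
            M[i][j] = matrix[ea[i - 1]][eb[j - 1]] + prev
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def spans_overlap(s1, s2):
    return s1[0] < s2[1] and s2[0] < s1[1]


def exhaustive_chain_best(hits):
    """Max total aligned length over all pairwise-compatible subsets."""
    n = len(hits)

    def conflict(h1, h2):
        return (spans_overlap(h1.query_span, h2.query_span)
                or spans_overlap(h1.subject_span, h2.subject_span))

    best = 0
    for mask in range(1 << n):
        members = [k for k in range(n) if mask >> k & 1]
        if any(conflict(hits[a], hits[b])
               for a, b in combinations(members, 2)):
            continue
        total = sum(hits[k].query_len + hits[k].subject_len
                    for k in members)
        best = max(best, total)
    return best


def fitch_exhaustive_min(tree, presence):
    """Minimum number of state changes over all internal labelings of a
    rooted tree (dendropy), for a binary leaf character."""
    internals = [nd for nd in tree.postorder_node_iter()
                 if not nd.is_leaf()]
    best = None
    for states in product([False, True], repeat=len(internals)):
        assign = dict(zip((id(nd) for nd in internals), states))
        changes = 0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is None:
                continue
            s = (presence[nd.taxon.label] if nd.is_leaf()
                 else assign[id(nd)])
            p = assign[id(nd.parent_node)]
            if s != p:
                changes += 1
        if best is None or changes < best:
            best = changes
    return best
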