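"""Independent reference implementation of divisive analysis clustering.

Deliberately written in plain Python (lists, explicit loops, recursion-free
bookkeeping) as an oracle for the vectorized package implementation. Both
follow the same published algorithm and the same tie-break (lowest object
index), so their flat partitions must agree at every cut level.
"""

from __future__ import annotations


def _diameter(d, cluster):
    best = 0.0
    for i in cluster:
        for j in cluster:
            if d[i][j] > best:
                best = d[i][j]
    return best


def _split(d, cluster):
    members = sorted(cluster)
    # seed: max average dissimilarity to cluster-mates, lowest index on ties
    best_avg, seed = -1.0, None
    for i in members:
        avg = sum(d[i][j] for j in members if j != i) / (len(members) - 1)
        if avg > best_avg + 1e-15:
            best_avg, seed = avg, i
    splinter = [seed]
    rest = [i for i in members if i != seed]
    while len(rest) > 1:
        best_diff, mover = 0.0, None
        for i in rest:
            to_rest = sum(d[i][j] for j in rest if j != i) / (len(rest) - 1)
            to_spl = sum(d[i][j] for j in splinter) / len(splinter)
            diff = to_rest - to_spl
            if diff > best_diff + 1e-15:
                best_diff, mover = diff, i
        if mover is None:
            break
        splinter.append(mover)
        rest.remove(mover)
    return splinter, rest


def diana_partitions(d):
    """Flat partitions at every k, as a list indexed by k-1.

    ``d`` is a full square dissimilarity matrix (list of lists or array).
    Partition at k is a list of sorted tuples.
    """
    n = len(d)
    clusters = [list(range(n))]
    partitions = [[tuple(range(n))]]
    while any(len(c) > 1 for c in clusters):
        best = (-1.0, None)
        for idx, c in enumerate(clusters):
            if len(c) < 2:
                continue
            diam = _diameter(d, c)
            key = (diam, -min(c))  # larger diameter first, lowest index on tie
            if best[1] is None or key > best[0]:
                best = (key, idx)
        idx = best[1]
        parent = clusters.pop(idx)
        left, right = _split(d, parent)
        clusters.append(left)
        clusters.append(right)
        partitions.append(
            sorted((tuple(sorted(c)) for c in clusters), key=lambda t: t[0])
        )
    return partitions
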