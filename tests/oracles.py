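"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's algorithms: the windowed-region oracle
enumerates every window explicitly, the patch oracle uses run-length grouping,
the enrichment oracle enumerates every draw, and the pooled-t oracle spells
out the textbook formula.
"""

from itertools import combinations, groupby
from math import comb, sqrt


def windowed_regions_oracle(labels, window=9, min_members=3, max_gap=5):
    """All maximal same-cluster member sets on one scaffold satisfying the
    documented windowed-region semantics: successive member gaps <= max_gap,
    and some window of ``window`` consecutive genes holds >= min_members of
    the set. Returns {(cluster, member_rank_tuple)}."""
    n = len(labels)
    out = set()
    for c in sorted({l for l in labels if l >= 0}):
        ranks = [i for i, l in enumerate(labels) if l == c]
        chains, cur = [], []
        for r in ranks:
            if cur and r - cur[-1] > max_gap:
                chains.append(cur)
                cur = []
            cur.append(r)
        if cur:
            chains.append(cur)
        for chain in chains:
            if len(chain) < min_members:
                continue
            members = set(chain)
            triggered = False
            for start in range(n):
                inside = members & set(range(start, start + window))
                if len(inside) >= min_members:
                    triggered = True
                    break
            if triggered:
                out.add((c, tuple(chain)))
    return out


def adjacent_patches_oracle(labels, min_run=3):
    """Maximal runs of rank-consecutive same-cluster genes, length >= min_run,
    via run-length grouping. Returns {(cluster, member_rank_tuple)}."""
    out = set()
    pos = 0
    for label, group in groupby(labels):
        run = len(list(group))
        if label >= 0 and run >= min_run:
            out.add((label, tuple(range(pos, pos + run))))
        pos += run
    return out


def hypergeom_tail_oracle(N, K, n, k):
    """P(overlap >= k) by exhaustive enumeration of all C(N, n) draws of n
    items from a universe of N with K class members."""
    if k <= 0:
        return 1.0
    hits = sum(
        1
        for draw in combinations(range(N), n)
        if sum(1 for x in draw if x < K) >= k
    )
    return hits / comb(N, n)


def pooled_t_oracle(xi, xc):
    """Textbook pooled two-sample t on two replicate vectors."""
    ni, nc = len(xi), len(xc)
    mi = sum(xi) / ni
    mc = sum(xc) / nc
    ssi = sum((x - mi) ** 2 for x in xi)
    ssc = sum((x - mc) ** 2 for x in xc)
    s2 = (ssi + ssc) / (ni + nc - 2)
    return (mi - mc) / sqrt(s2 * (1.0 / ni + 1.0 / nc))


def pearson_oracle(x, y):
    """Textbook Pearson correlation on two equal-length vectors."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / sqrt(vx * vy)


def random_scaffold(rng, max_genes=60, max_clusters=6):
    """Random per-rank cluster labels (-1 = unassigned) for oracle tests."""
    n = int(rng.integers(5, max_genes + 1))
    n_clusters = int(rng.integers(1, max_clusters + 1))
    # mix isolated labels with planted stretches so both rules fire
    labels = rng.choice(
        list(range(-1, n_clusters)), size=n, p=None
    ).tolist()
    if n >= 10 and rng.random() < 0.7:
        start = int(rng.integers(0, n - 5))
        labels[start : start + 5] = [int(rng.integers(0, n_clusters))] * 5
    return labels
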