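"""Independent brute-force reference implementations used to check the package.

These deliberately re-derive results from first principles (literal rule
scans, interval stabbing, exhaustive enumeration, naive agglomeration)
and share no code with the implementation under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def depth_oracle(pairs, window_length: int, allow_soft_clips: bool = False):
    """Brute-force per-base pair depth by interval stabbing over retained pairs.

    For each valid EQ/FR pair the per-pair footprint is the union of
    both mapped spans, the inter-mate gap, and any soft-clip projections
    (every base counted once per pair). Returns the expected
    total-coverage array.
    """
    depth = np.zeros(window_length, dtype=int)
    for pair in pairs:
        bases = set()
        for span in (pair.f_span, pair.r_span):
            if span is not None:
                bases.update(range(max(0, span[0]), min(window_length, span[1])))
        if pair.f_span is not None and pair.r_span is not None:
            fe, rs = pair.f_span[1], pair.r_span[0]
            if fe < rs:
                bases.update(range(max(0, fe), min(window_length, rs)))
        for span in pair.clipped_spans:
            bases.update(range(max(0, span[0]), min(window_length, span[1])))
        for b in bases:
            depth[b] += 1
    return depth


def peak_scan_oracle(conv, zero_band: float = 0.1):
    """Literal-rules peak scan: O(n*w) application of the published criteria.

    Summits are local extrema (plateaus keyed left-most, zero-padded
    boundaries) with |amplitude| on or outside the open zero region.
    Regions extend while the amplitude keeps the summit sign, stays on
    or outside the zero region, and decreases non-strictly in magnitude
    away from the summit; the valley base shared between adjacent
    same-sign peaks goes to the left peak. Returns a list of
    (summit, left, right, amplitude) tuples.
    """
    conv = [float(v) for v in conv]
    n = len(conv)

    def at(i):
        return conv[i] if 0 <= i < n else 0.0

    # summits: left-most member of each plateau that is a strict local extremum
    summits = []
    for i in range(n):
        v = conv[i]
        if abs(v) < zero_band:
            continue
        if at(i - 1) == v:  # not the left-most member of its plateau
            continue
        j = i
        while j + 1 < n and conv[j + 1] == v:
            j += 1
        prev, nxt = at(i - 1), at(j + 1)
        if (v > 0 and prev < v and nxt < v) or (v < 0 and prev > v and nxt > v):
            summits.append(i)

    results = []
    claimed_until = 0
    for s in summits:
        sign = 1 if conv[s] > 0 else -1

        def ok(i, inner):
            # inner = the already-accepted neighbor closer to the summit
            v = conv[i]
            if sign * v < zero_band:
                return False
            return abs(v) <= abs(conv[inner])

        left = s
        while left - 1 >= claimed_until and ok(left - 1, left):
            left -= 1
        right = s + 1
        while right < n and ok(right, right - 1):
            right += 1
        claimed_until = right
        results.append((s, left, right, conv[s]))
    return results


def mannwhitney_less_oracle(x, y) -> float:
    """Exact one-tailed (x stochastically smaller) Mann-Whitney p by enumeration.

    Assumes no ties. Enumerates every assignment of the pooled values
    into groups of the observed sizes and counts assignments with a U
    statistic at most the observed one.
    """
    x, y = list(x), list(y)
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "oracle assumes untied values"
    n = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if u_stat(xs, ys) <= u_obs:
            count += 1
    return count / total


def complete_linkage_oracle(positions, threshold: float):
    """Naive agglomerative complete-linkage clustering with a distance cut.

    Repeatedly merges the pair of clusters with the smallest maximum
    pairwise distance while that distance is at most the threshold.
    Returns a set of frozensets of member indices.
    """
    clusters = [frozenset([i]) for i in range(len(positions))]
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = max(
                abs(positions[i] - positions[j])
                for i in clusters[a]
                for j in clusters[b]
            )
            key = (d, min(min(clusters[a]), min(clusters[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        if d > threshold:
            break
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return set(clusters)
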