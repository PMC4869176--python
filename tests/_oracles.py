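"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the Fisher oracle works
in exact integer/rational arithmetic, the clustering and overlap oracles are
quadratic enumerations.
"""

from fractions import Fraction
from math import comb


def fisher_exact_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by exhaustive hypergeometric enumeration in
    exact arithmetic: sum the point probabilities of every table with the
    same margins whose probability does not exceed the observed one."""
    m, n, k = a + b, c + d, a + c
    nums = {x: comb(m, x) * comb(n, k - x)
            for x in range(max(0, k - n), min(k, m) + 1)}
    obs = nums[a]
    total = comb(m + n, k)
    return float(Fraction(sum(v for v in nums.values() if v <= obs), total))


def cluster_oracle(positions, min_sites: int, max_gap: int):
    """Every maximal gap-bounded run of sorted positions, by O(n^2) scan;
    returns (start_pos, end_pos_exclusive, n_sites) for runs >= min_sites."""
    runs = []
    i = 0
    while i < len(positions):
        j = i
        while j + 1 < len(positions) and positions[j + 1] - positions[j] <= max_gap:
            j += 1
        if j - i + 1 >= min_sites:
            runs.append((positions[i], positions[j] + 1, j - i + 1))
        i = j + 1
    return runs


def overlap_pairs_oracle(regions_a, regions_b, min_overlap_bp: int = 1):
    """All-pairs interval intersection >= min_overlap_bp; regions are
    (chrom, start, end) tuples; returns sorted (i, j) index pairs."""
    pairs = []
    for i, (ca, sa, ea) in enumerate(regions_a):
        for j, (cb, sb, eb) in enumerate(regions_b):
            if ca == cb and min(ea, eb) - max(sa, sb) >= min_overlap_bp:
                pairs.append((i, j))
    return sorted(pairs)


def stab_oracle(point, intervals_by_label, precedence):
    """Highest-precedence label whose raw interval list covers the point."""
    for label in precedence:
        if label == "intergenic":
            continue
        for s, e in intervals_by_label.get(label, []):
            if s <= point < e:
                return label
    return "intergenic"


def bh_oracle(pvalues):
    """Benjamini-Hochberg step-up by direct evaluation of the formula."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q[i] = running
    return q
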