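"""Independent brute-force oracles used to cross-check the implementations.

These deliberately share no code with the package: set algebra by double
loop, exact contingency probabilities with rational arithmetic, rank
statistics recomputed from first principles.
"""

from fractions import Fraction
from itertools import product
from math import comb


def apply_edit(context: str, context_start: int, pos: int, ref: str, alt: str) -> str:
    """Apply a variant to an explicit sequence context (1-based coordinates)."""
    offset = pos - context_start
    assert 0 <= offset and offset + len(ref) <= len(context)
    assert context[offset : offset + len(ref)] == ref
    return context[:offset] + alt + context[offset + len(ref) :]


def brute_force_match(calls_a, calls_b):
    """Double-loop matcher on (chrom, pos, ref, alt) keys with dedup."""
    seen_a, uniq_a = set(), []
    for c in calls_a:
        if c.key not in seen_a:
            seen_a.add(c.key)
            uniq_a.append(c)
    seen_b, uniq_b = set(), []
    for c in calls_b:
        if c.key not in seen_b:
            seen_b.add(c.key)
            uniq_b.append(c)
    both, only_a = [], []
    for ca in uniq_a:
        partner = None
        for cb in uniq_b:
            if ca.key == cb.key:
                partner = cb
                break
        if partner is None:
            only_a.append(ca)
        else:
            both.append((ca, partner))
    only_b = [cb for cb in uniq_b if all(cb.key != ca.key for ca in uniq_a)]
    return both, only_a, only_b


def exact_2xk_pvalue(table) -> Fraction:
    """Two-sided exact independence test by full rational enumeration.

    Enumerates every first row compatible with the margins, computing each
    table's conditional probability as a Fraction, and sums those with
    probability <= the observed table's.
    """
    row0, row1 = [list(map(int, r)) for r in table]
    cols = [a + b for a, b in zip(row0, row1)]
    r0 = sum(row0)
    n = sum(cols)

    def prob(first_row) -> Fraction:
        num = 1
        for a, c in zip(first_row, cols):
            num *= comb(c, a)
        return Fraction(num, comb(n, r0))

    p_obs = prob(row0)
    total = Fraction(0)
    for combo in product(*[range(c + 1) for c in cols[:-1]]):
        last = r0 - sum(combo)
        if 0 <= last <= cols[-1]:
            p = prob(list(combo) + [last])
            if p <= p_obs:
                total += p
    return total


def rank_then_pearson(x, y) -> float:
    """Spearman r recomputed as Pearson correlation of average ranks."""
    import numpy as np

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    return float(np.corrcoef(rx, ry)[0, 1])
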