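"""Independent brute-force oracles used by the test suite.

Deliberately written without reusing the package's vectorized machinery:
matchings are enumerated by a different recursion, probabilities are
exact `fractions.Fraction` arithmetic, and distributions are built by
explicit enumeration of transmissions.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np


def all_matchings(items):
    """All perfect matchings of a list, by leftmost-first recursion."""
    items = list(items)
    if not items:
        return [[]]
    first, rest = items[0], items[1:]
    out = []
    for k in range(len(rest)):
        pair = (first, rest[k])
        remaining = rest[:k] + rest[k + 1 :]
        for tail in all_matchings(remaining):
            out.append([pair] + tail)
    return out


def gamete_dosage_bruteforce(ploidy, dosage):
    """Gamete dosage pmf by enumerating every homologue subset."""
    carriers = set(range(dosage))
    counts = {}
    subsets = list(combinations(range(ploidy), ploidy // 2))
    for s in subsets:
        k = len(carriers & set(s))
        counts[k] = counts.get(k, 0) + 1
    return {k: v / len(subsets) for k, v in counts.items()}


def two_locus_bruteforce(ploidy, da, db, shared, r):
    """Joint transmitted-dosage pmf of one parent at recombination
    fraction r, by exact enumeration over pairings and per-bivalent
    transmissions (Fraction arithmetic, float r folded in at the end)."""
    m = ploidy // 2
    a_set = set(range(da))
    b_set = set(range(shared)) | set(range(da, da + db - shared))
    rr = Fraction(r).limit_denominator(10**9)
    stay = (1 - rr) / 2
    switch = rr / 2
    pairings = all_matchings(range(ploidy))
    joint = np.zeros((m + 1, m + 1), dtype=object)
    joint[:] = Fraction(0)
    for pairing in pairings:
        # distribution over (a, b) contributed by this pairing
        dists = []
        for i, j in pairing:
            d = {}
            for start, other in ((i, j), (j, i)):
                a_c = int(start in a_set)
                for target, pr in ((start, stay), (other, switch)):
                    key = (a_c, int(target in b_set))
                    d[key] = d.get(key, Fraction(0)) + pr
            dists.append(d)
        acc = {(0, 0): Fraction(1)}
        for d in dists:
            nxt = {}
            for (a0, b0), p0 in acc.items():
                for (a1, b1), p1 in d.items():
                    key = (a0 + a1, b0 + b1)
                    nxt[key] = nxt.get(key, Fraction(0)) + p0 * p1
            acc = nxt
        for (a, b), p in acc.items():
            joint[a, b] += p
    out = np.zeros((m + 1, m + 1))
    for a in range(m + 1):
        for b in range(m + 1):
            out[a, b] = float(joint[a, b] / len(pairings))
    return out
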