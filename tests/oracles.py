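"""Independent brute-force oracles used to validate the fast implementations.

These deliberately re-derive each quantity from its definition (exact
rational running sums, exhaustive enumeration of draws) and never call the
code paths they check.
"""

from fractions import Fraction
from itertools import combinations


def es_bruteforce(S, features):
    """KS enrichment score by walking the ranking with exact rationals.

    Returns a Fraction: the running-sum deviation of maximum absolute value,
    positive extreme preferred on an exact magnitude tie.
    """
    S = set(S)
    n = len(features)
    k = len(S)
    hit = Fraction(1, k)
    miss = Fraction(1, n - k)
    running = Fraction(0)
    best = Fraction(0)
    for f in features:
        running = running + hit if f in S else running - miss
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def hypergeom_upper_enumerate(k, K, n, N_u):
    """P(X >= k) by enumerating every size-n draw from the population."""
    population = range(N_u)
    successes = set(range(K))
    favorable = 0
    total = 0
    for draw in combinations(population, n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            favorable += 1
    return Fraction(favorable, total)
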