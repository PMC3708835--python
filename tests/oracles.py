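"""Independent brute-force oracles used across the suite.

The Fisher oracle enumerates the hypergeometric distribution of margin-fixed
2x2 tables in exact integer arithmetic; it never calls the code path it
checks.
"""

from fractions import Fraction
from math import comb


def fisher_exact_oracle(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Exact Fisher p for [[a, b], [c, d]] by full hypergeometric enumeration.

    ``greater`` tests enrichment of the top-left cell (odds ratio > 1).
    Two-sided sums all tables whose probability does not exceed the observed
    table's (with a tiny relative tolerance for representability).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    pmf = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom) for k in range(k_lo, k_hi + 1)
    }
    p_obs = pmf[a]
    if alternative == "greater":
        total = sum(p for k, p in pmf.items() if k >= a)
    elif alternative == "less":
        total = sum(p for k, p in pmf.items() if k <= a)
    elif alternative == "two-sided":
        cutoff = p_obs * (1 + Fraction(1, 10**9))
        total = sum(p for p in pmf.values() if p <= cutoff)
    else:
        raise ValueError(alternative)
    return float(min(total, Fraction(1)))


def fisher_pvalues_for_margins(r1: int, r2: int, c1: int):
    """Exact p-values for every table with the given margins, by enumeration.

    Returns {a: (two_sided_p, greater_p)} over all feasible top-left cells.
    Weights are exact integers; the two-sided rule sums tables whose
    hypergeometric weight does not exceed the observed weight (tiny relative
    tolerance for representability, as in the single-table oracle).
    """
    n = r1 + r2
    denom = comb(n, c1)
    k_lo = max(0, c1 - r2)
    k_hi = min(r1, c1)
    ks = range(k_lo, k_hi + 1)
    w = {k: comb(r1, k) * comb(r2, c1 - k) for k in ks}
    out = {}
    for a in ks:
        wa = w[a]
        two = sum(wk for wk in w.values() if wk * 10**9 <= wa * (10**9 + 1))
        greater = sum(w[k] for k in ks if k >= a)
        out[a] = (min(two / denom, 1.0), min(greater / denom, 1.0))
    return out


def all_tables_with_margins_up_to(max_margin: int):
    """Yield (a, b, c, d) for every 2x2 whose four margins are all <= max_margin."""
    for r1 in range(max_margin + 1):
        for r2 in range(max_margin + 1):
            n = r1 + r2
            for c1 in range(max(0, n - max_margin), min(n, max_margin) + 1):
                for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                    yield a, r1 - a, c1 - a, r2 - (c1 - a)
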