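"""Independent exact-arithmetic oracles for the Bayesian arc score.

Everything here deliberately avoids the package's log-gamma code path:
marginal likelihoods are exact rational numbers built from rising
factorials (Gamma(a + n) / Gamma(a) = a (a+1) ... (a+n-1), exact for
rational a), and posteriors are normalised in Fraction arithmetic.
"""

from __future__ import annotations

import math
from fractions import Fraction


def rising_factorial(a: Fraction, n: int) -> Fraction:
    out = Fraction(1)
    for i in range(n):
        out *= a + i
    return out


def exact_marginal_likelihood(counts, alpha) -> Fraction:
    """P(D | model) for a count table (rows = cause states, cols = effect
    states) with uniform Dirichlet pseudo-count ``alpha`` per cell."""
    a = Fraction(alpha)
    p = Fraction(1)
    for row in counts:
        n_j = sum(row)
        a_j = a * len(row)
        p /= rising_factorial(a_j, n_j)
        for n_jk in row:
            p *= rising_factorial(a, n_jk)
    return p


def exact_log_marginal_likelihood(counts, alpha) -> float:
    p = exact_marginal_likelihood(counts, alpha)
    return math.log(p.numerator) - math.log(p.denominator)


def naive_tumor_posteriors(sga_rows, deg_rows, tumor_idx, alpha=1) -> dict:
    """Posteriors over {A0} + the tumor's SGAs for each of its DEGs,
    computed by direct enumeration in exact rational arithmetic with a
    uniform prior. ``sga_rows``/``deg_rows`` are lists of 0/1 lists
    (tumors x genes); gene names are their column indices.

    Returns {effect index: {cause: Fraction posterior}} with cause "A0"
    or an SGA column index.
    """
    n = len(sga_rows)
    n_sga = len(sga_rows[0])
    n_deg = len(deg_rows[0])
    out: dict[int, dict] = {}
    host = [h for h in range(n_sga) if sga_rows[tumor_idx][h] == 1]
    for e in range(n_deg):
        if deg_rows[tumor_idx][e] != 1:
            continue
        scores: dict = {}
        # cause-absent model: one block over all tumors
        k1 = sum(deg_rows[t][e] for t in range(n))
        scores["A0"] = exact_marginal_likelihood([[n - k1, k1]], alpha)
        for h in host:
            tab = [[0, 0], [0, 0]]
            for t in range(n):
                tab[sga_rows[t][h]][deg_rows[t][e]] += 1
            scores[h] = exact_marginal_likelihood(tab, alpha)
        z = sum(scores.values())  # uniform prior cancels
        out[e] = {c: s / z for c, s in scores.items()}
    return out
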